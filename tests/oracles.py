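"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the code paths (and, where feasible, the
libraries) they are used to check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration in exact arithmetic.

    Sums the conditional hypergeometric probabilities of every table with
    the observed margins whose point probability does not exceed the
    observed table's.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def point(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = point(a)
    total = Fraction(0)
    for x in range(lo, hi + 1):
        p = point(x)
        if p <= p_obs:
            total += p
    return total


def auc_pair_counting(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic over positive/negative pairs."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def flood_fill_label(binary: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a 3-D binary grid by explicit flood fill."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    remaining = set(map(tuple, np.argwhere(binary)))
    components = []
    while remaining:
        seed = remaining.pop()
        stack, comp = [seed], {seed}
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        components.append(frozenset(comp))
    return components


def hungarian_match_correlation(S_true: np.ndarray, S_est: np.ndarray) -> np.ndarray:
    """Best signed-permutation match: |Pearson r| per matched pair."""
    from scipy.optimize import linear_sum_assignment

    k = S_true.shape[0]
    r = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            r[i, j] = abs(np.corrcoef(S_true[i], S_est[j])[0, 1])
    rows, cols = linear_sum_assignment(-r)
    return r[rows, cols]


def trilinear_1d(values: np.ndarray, x: float) -> float:
    """Closed-form linear interpolation of a 1-D sample sequence."""
    i0 = int(np.floor(x))
    if i0 >= len(values) - 1:
        return float(values[-1])
    if i0 < 0:
        return float(values[0])
    frac = x - i0
    return float(values[i0] * (1 - frac) + values[i0 + 1] * frac)
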