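"""Reliability-clustered spatial ICA and cross-cohort coefficient projection.

The training matrix X (subjects x voxels) is modeled as X = A @ S with
statistically independent spatial sources S (components x voxels) and
subject-specific mixing coefficients A. To stabilize the rotational
ambiguity of fixed-point ICA, the decomposition is repeated from many
random initializations on a shared whitening, the pooled components are
clustered by absolute spatial correlation, and each cluster is summarized
by its centrotype — the member most similar on average to the rest of its
cluster. New cohorts are projected into the component space via the
Moore-Penrose pseudoinverse, A_new = (X_new - mean_train) @ pinv(S), and
coefficient columns are standardized with *training* statistics so the
classifier never sees test-derived scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import fastica
from sklearn.exceptions import ConvergenceWarning

from .preprocess import SubjectMatrix

__all__ = [
    "ReliableSpatialICA",
    "CoefficientMatrix",
    "CoefficientScaler",
    "cluster_components",
    "decompose",
    "project",
    "normalize_coefficients",
]

PINV_RCOND = 1e-10


@dataclass
class CoefficientMatrix:
    """Subjects x components mixing coefficients.

    ``norm_mean``/``norm_sd`` hold the per-column training statistics once
    normalized; test-cohort normalization always reuses the training
    statistics. ``role`` is "training" or "testing".
    """

    A: np.ndarray
    role: str = "training"
    norm_mean: np.ndarray | None = None
    norm_sd: np.ndarray | None = None
    subject_ids: list | None = None

    @property
    def n_components(self) -> int:
        return self.A.shape[1]


def _as_array(X) -> np.ndarray:
    if isinstance(X, SubjectMatrix):
        return X.values
    return np.asarray(X, dtype=np.float64)


def run_seed(master_seed: int, run_index: int) -> int:
    """Per-run seed derived from the master seed by a counter scheme."""
    return int(
        np.random.SeedSequence([int(master_seed), int(run_index)]).generate_state(1)[0]
        % (2**31)
    )


def component_similarity(pooled: np.ndarray) -> np.ndarray:
    """Pairwise |Pearson r| between component images (sign-invariant)."""
    z = pooled - pooled.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(z, axis=1)
    norms[norms == 0] = 1.0
    z = z / norms[:, None]
    sim = np.abs(z @ z.T)
    np.clip(sim, 0.0, 1.0, out=sim)
    np.fill_diagonal(sim, 1.0)
    return sim


def cluster_assignments(pooled: np.ndarray, n_clusters: int) -> np.ndarray:
    """Average-linkage cluster labels on distance 1 - |Pearson r|."""
    pooled = np.asarray(pooled, dtype=np.float64)
    n = pooled.shape[0]
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds pooled count {n}")
    sim = component_similarity(pooled)
    dist = 1.0 - sim
    dist = (dist + dist.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    return fcluster(
        linkage(squareform(dist, checks=False), method="average"),
        t=n_clusters,
        criterion="maxclust",
    )


def cluster_components(
    pooled: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster pooled components by |Pearson r| and pick centrotypes.

    Similarity between two component images is the absolute Pearson
    correlation across voxels; clustering is agglomerative with average
    linkage on distance 1 - |r|, cut at ``n_clusters``. The centrotype of
    a cluster is the member maximizing the sum of similarities to the
    other members (a singleton's quality is defined as 1).

    Returns
    -------
    centrotypes : ndarray, shape (n_clusters, V)
    quality : ndarray, shape (n_clusters,)
        Mean intra-cluster similarity of each centrotype.
    """
    pooled = np.asarray(pooled, dtype=np.float64)
    sim = component_similarity(pooled)
    labels = cluster_assignments(pooled, n_clusters)
    centrotypes, quality, order = [], [], []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if members.size == 1:
            best = members[0]
            q = 1.0
        else:
            sub = sim[np.ix_(members, members)]
            sums = sub.sum(axis=1) - 1.0  # exclude self-similarity
            best = members[int(np.argmax(sums))]
            q = float(sums.max() / (members.size - 1))
        centrotypes.append(pooled[best])
        quality.append(q)
        order.append(best)
    # deterministic output order: by first appearance of the centrotype
    idx = np.argsort(order)
    return np.asarray(centrotypes)[idx], np.asarray(quality)[idx]


class ReliableSpatialICA(BaseEstimator, TransformerMixin):
    """Repeated fixed-point spatial ICA with similarity clustering.

    Parameters
    ----------
    n_components : int or None
        Number of spatial components (and clusters). None resolves to the
        number of training subjects; note that voxel-wise centering caps
        the usable rank at n_subjects - 1, so an explicit smaller value is
        usually required.
    n_runs : int, default 200
        Number of repeated ICA runs pooled before clustering.
    random_state : int, default 0
        Master seed; per-run seeds are derived by a counter scheme.
    max_iter, tol : fixed-point iteration controls per run.

    Attributes
    ----------
    components_ : ndarray, shape (n_components, V)
        Centrotype spatial components, standardized to zero mean and unit
        variance over voxels.
    cluster_quality_ : ndarray, shape (n_components,)
        Mean intra-cluster similarity of each centrotype.
    mean_ : ndarray, shape (V,)
        Training voxel means; reused to center any projected cohort.
    whitening_ : dict
        The shared PCA whitening (matrix ``K`` and singular values) used
        by every run, recorded for reproducibility.
    """

    def __init__(
        self,
        n_components: int | None = None,
        n_runs: int = 200,
        random_state: int = 0,
        max_iter: int = 200,
        tol: float = 1e-4,
    ):
        self.n_components = n_components
        self.n_runs = n_runs
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting -------------------------------------------------------

    def fit(self, X, y=None):
        Xa = _as_array(X)
        n, V = Xa.shape
        k = n if self.n_components is None else int(self.n_components)
        if k > n:
            raise ValueError(f"n_components={k} exceeds n_subjects={n}")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        self.mean_ = Xa.mean(axis=0)
        Xc = Xa - self.mean_
        # shared whitening: PCA of the centered training matrix
        U, sing, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank = int(np.sum(sing > sing[0] * 1e-10)) if sing.size else 0
        if rank < k:
            raise ValueError(
                f"centered training matrix has rank {rank} < n_components={k}; "
                "reduce n_components (voxel-wise centering removes one degree "
                "of freedom)"
            )
        # whitened voxel-sample representation, shape (V, k), unit covariance
        Z = np.sqrt(V) * Vt[:k].T
        self.whitening_ = {
            "singular_values": sing[:k].copy(),
            "n_voxels": V,
        }
        pooled = np.empty((self.n_runs * k, V))
        rng_master = int(self.random_state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for r in range(self.n_runs):
                rng = np.random.default_rng(run_seed(rng_master, r))
                w_init = rng.normal(size=(k, k))
                _, _, S_run = fastica(
                    Z,
                    whiten=False,
                    fun="logcosh",
                    w_init=w_init,
                    max_iter=self.max_iter,
                    tol=self.tol,
                )
                pooled[r * k : (r + 1) * k] = S_run.T
        centrotypes, quality = cluster_components(pooled, k)
        # standardize each component image over voxels
        centrotypes = centrotypes - centrotypes.mean(axis=1, keepdims=True)
        sd = centrotypes.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        self.components_ = centrotypes / sd
        self.cluster_quality_ = quality
        self.n_components_ = k
        self.pseudoinverse_ = np.linalg.pinv(self.components_, rcond=PINV_RCOND)
        return self

    # -- projection ----------------------------------------------------

    def transform(self, X, role: str = "testing") -> CoefficientMatrix:
        """Project a cohort into the component space: A = Xc @ pinv(S).

        Centering uses the *training* voxel means stored at fit time.
        """
        if not hasattr(self, "components_"):
            raise ValueError("ReliableSpatialICA is not fitted")
        Xa = _as_array(X)
        if Xa.shape[1] != self.components_.shape[1]:
            raise ValueError(
                f"voxel count {Xa.shape[1]} does not match the fitted "
                f"components' {self.components_.shape[1]}"
            )
        A = (Xa - self.mean_) @ self.pseudoinverse_
        ids = X.subject_ids if isinstance(X, SubjectMatrix) else None
        return CoefficientMatrix(A=A, role=role, subject_ids=ids)

    def fit_transform(self, X, y=None, **kwargs) -> CoefficientMatrix:
        return self.fit(X).transform(X, role="training")


class CoefficientScaler(BaseEstimator, TransformerMixin):
    """Column standardization of coefficients by training mean / sample SD.

    Fit on the training coefficient matrix; ``transform`` then shifts and
    scales any matrix (training or testing) by the stored training
    statistics. Sample SD uses the n-1 denominator.
    """

    def fit(self, A: CoefficientMatrix | np.ndarray, y=None):
        arr = A.A if isinstance(A, CoefficientMatrix) else np.asarray(A, float)
        if arr.shape[0] < 2:
            raise ValueError("need at least 2 training rows to standardize")
        self.mean_ = arr.mean(axis=0)
        self.sd_ = arr.std(axis=0, ddof=1)
        zero = np.flatnonzero(self.sd_ == 0)
        if zero.size:
            raise ValueError(
                f"training coefficient column(s) {zero.tolist()} have zero SD"
            )
        return self

    def transform(self, A: CoefficientMatrix | np.ndarray):
        if isinstance(A, CoefficientMatrix):
            return CoefficientMatrix(
                A=(A.A - self.mean_) / self.sd_,
                role=A.role,
                norm_mean=self.mean_.copy(),
                norm_sd=self.sd_.copy(),
                subject_ids=A.subject_ids,
            )
        return (np.asarray(A, float) - self.mean_) / self.sd_


# -- functional wrappers over the estimators ---------------------------


def decompose(
    X_train, n_components: int | None = None, n_runs: int = 200, seed: int = 0
) -> ReliableSpatialICA:
    """Fit the reliability-clustered spatial ICA on the training matrix."""
    return ReliableSpatialICA(
        n_components=n_components, n_runs=n_runs, random_state=seed
    ).fit(X_train)


def project(X, model: ReliableSpatialICA, role: str = "testing") -> CoefficientMatrix:
    return model.transform(X, role=role)


def normalize_coefficients(
    A_train: CoefficientMatrix, A_test: CoefficientMatrix
) -> tuple[CoefficientMatrix, CoefficientMatrix]:
    """Standardize training columns; shift/scale test by training stats."""
    if A_train.n_components != A_test.n_components:
        raise ValueError("component count mismatch between train and test")
    scaler = CoefficientScaler().fit(A_train)
    return scaler.transform(A_train), scaler.transform(A_test)
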