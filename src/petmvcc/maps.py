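"""Sign-corrected component z-maps, cluster-extent thresholding, peak tables.

The components driving classification are the ones with the largest
absolute logistic weights (about the top 5%). Each selected component
image is multiplied by the sign of its weight — after which positive map
values always mean hypermetabolism in patients — standardized to a
z-score map over the gray-matter mask, and thresholded: voxels with
|z| above the threshold are grouped into connected clusters (positive and
negative exceedances separately), clusters below the minimum extent are
discarded, and local peaks are reported in mm coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import Volume

__all__ = [
    "ZMap",
    "ClusterTable",
    "rank_weights",
    "sign_correct",
    "zscore_map",
    "threshold_clusters",
    "find_peaks",
    "label_regions",
]

CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class ZMap:
    """Standardized component image over the mask (off-mask voxels are 0)."""

    volume: Volume
    mask: Volume
    component_id: int
    weight_sign: int


@dataclass
class ClusterTable:
    """Suprathreshold clusters of one z-map, with per-map settings.

    ``clusters`` is a list of dicts with keys: cluster_id, direction
    ('+'/'-'), extent_voxels, voxels (ndarray of ijk), and, after peak
    finding, peaks (list of dicts with z, x_mm, y_mm, z_mm, region).
    """

    component_id: int
    z_threshold: float
    min_extent: int
    connectivity: int
    clusters: list = field(default_factory=list)
    grid: Volume | None = None  # source grid geometry, for atlas lookups

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cl in self.clusters:
            peaks = cl.get("peaks") or [None]
            for pk in peaks:
                rows.append(
                    {
                        # 1-based IC label, matching the ICn file naming
                        "component": self.component_id + 1,
                        "cluster_id": cl["cluster_id"],
                        "direction": cl["direction"],
                        "extent_voxels": cl["extent_voxels"],
                        "peak_z": None if pk is None else pk["z"],
                        "x_mm": None if pk is None else pk["x_mm"],
                        "y_mm": None if pk is None else pk["y_mm"],
                        "z_mm": None if pk is None else pk["z_mm"],
                        "region": None if pk is None else pk.get("region", "-"),
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "component", "cluster_id", "direction", "extent_voxels",
                "peak_z", "x_mm", "y_mm", "z_mm", "region",
            ],
        )


def rank_weights(weights: np.ndarray, top_fraction: float = 0.05) -> tuple[list[int], list[int]]:
    """Components ranked by |weight| descending; select the top fraction.

    Returns (selected ids, full ranking). The selected count is
    ceil(top_fraction * k), so 34 weights at 5% give the top two. Ties in
    |weight| break toward the smaller component id.
    """
    w = np.asarray(weights, dtype=np.float64)
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    k = w.size
    order = np.lexsort((np.arange(k), -np.abs(w)))
    n_top = int(ceil(top_fraction * k))
    return list(order[:n_top]), list(order)


def sign_correct(component_image: np.ndarray, weight: float) -> np.ndarray:
    """Multiply the component image by the sign of its classifier weight."""
    if weight == 0:
        raise ValueError("weight is exactly zero: direction is uninterpretable")
    return np.sign(weight) * np.asarray(component_image, dtype=np.float64)


def zscore_map(
    component_image, mask: Volume, component_id: int = 0, weight_sign: int = 1
) -> ZMap:
    """Standardize a component image to z-scores over mask voxels only."""
    binary = mask.data > 0.5
    if binary.sum() < 2:
        raise ValueError("mask must contain at least 2 voxels")
    img = np.asarray(component_image, dtype=np.float64)
    if img.shape != mask.shape:
        raise ValueError("component image grid does not match the mask")
    vals = img[binary]
    sd = vals.std()
    if sd == 0:
        raise ValueError("zero in-mask standard deviation")
    z = np.zeros(mask.shape)
    z[binary] = (vals - vals.mean()) / sd
    return ZMap(
        volume=mask.copy(data=z),
        mask=mask,
        component_id=component_id,
        weight_sign=int(np.sign(weight_sign)) or 1,
    )


def threshold_clusters(
    zmap: ZMap,
    z_threshold: float = 2.58,
    min_extent: int = 50,
    connectivity: int = 18,
) -> ClusterTable:
    """Connected suprathreshold clusters, per sign, above a minimum extent.

    Positive (z > threshold) and negative (z < -threshold) exceedance
    sets are labeled separately and never merged across sign.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if min_extent < 1:
        raise ValueError("min_extent must be >= 1")
    if connectivity not in CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(CONNECTIVITY_STRUCTS)}")
    struct = CONNECTIVITY_STRUCTS[connectivity]
    z = zmap.volume.data
    table = ClusterTable(
        component_id=zmap.component_id,
        z_threshold=float(z_threshold),
        min_extent=int(min_extent),
        connectivity=int(connectivity),
        grid=zmap.volume,
    )
    next_id = 1
    for direction, exceed in (("+", z > z_threshold), ("-", z < -z_threshold)):
        labeled, n_lab = ndimage.label(exceed, structure=struct)
        for lab in range(1, n_lab + 1):
            voxels = np.argwhere(labeled == lab)
            if voxels.shape[0] < min_extent:
                continue
            table.clusters.append(
                {
                    "cluster_id": next_id,
                    "direction": direction,
                    "extent_voxels": int(voxels.shape[0]),
                    "voxels": voxels,
                }
            )
            next_id += 1
    return table


def find_peaks(
    zmap: ZMap, table: ClusterTable, min_separation_mm: float = 8.0
) -> ClusterTable:
    """Annotate each cluster with its local |z| peaks in mm coordinates.

    A peak is a voxel whose |z| is >= that of all its neighbors under the
    table's connectivity; peaks within ``min_separation_mm`` of a stronger
    peak in the same cluster are suppressed.
    """
    z = zmap.volume.data
    absz = np.abs(z)
    struct = CONNECTIVITY_STRUCTS[table.connectivity]
    neighborhood_max = ndimage.maximum_filter(absz, footprint=struct, mode="constant")
    vol = zmap.volume
    for cl in table.clusters:
        vox = cl["voxels"]
        in_cluster = absz[tuple(vox.T)] >= neighborhood_max[tuple(vox.T)] - 1e-12
        candidates = vox[in_cluster]
        if candidates.shape[0] == 0:  # plateau edge case: take the argmax voxel
            candidates = vox[[int(np.argmax(absz[tuple(vox.T)]))]]
        zvals = z[tuple(candidates.T)]
        order = np.argsort(-np.abs(zvals), kind="stable")
        kept_ijk, kept = [], []
        for idx in order:
            mm = vol.index_to_mm(candidates[idx])
            if any(
                np.linalg.norm(mm - prev) < min_separation_mm for prev in kept_ijk
            ):
                continue
            kept_ijk.append(mm)
            kept.append(
                {
                    "z": float(zvals[idx]),
                    "x_mm": float(mm[0]),
                    "y_mm": float(mm[1]),
                    "z_mm": float(mm[2]),
                    "ijk": candidates[idx].tolist(),
                }
            )
        cl["peaks"] = kept
    return table


def label_regions(
    table: ClusterTable, label_volume: Volume, label_names: dict
) -> ClusterTable:
    """Annotate peaks with the atlas label at their voxel ('-' if none).

    ``label_names`` maps integer label values to region names; label 0 or
    a value missing from the map annotates as '-'.
    """
    if table.grid is not None and not label_volume.same_grid(table.grid):
        raise ValueError("label volume grid does not match the z-map grid")
    for cl in table.clusters:
        for pk in cl.get("peaks", []):
            ijk = pk.get("ijk")
            if ijk is None:
                continue
            val = int(round(float(label_volume.data[tuple(ijk)])))
            pk["region"] = label_names.get(val, "-") if val != 0 else "-"
    return table
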