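"""PET volume preprocessing: resample, smooth, intensity-normalize, vectorize.

The stage order used throughout the package is

    resample -> smooth -> intensity-normalize -> mask/vectorize

producing the subjects x in-mask-voxels matrix that the spatial ICA
decomposes. Intensity normalization divides each voxel by the mean of the
brightest 20% of the voxels exceeding one-eighth of the image mean, the
usual reference-free normalization for brain FDG-PET.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .volume import Volume

__all__ = [
    "SubjectMatrix",
    "resample_volume",
    "smooth_volume",
    "intensity_normalize",
    "build_subject_matrix",
    "PETPreprocessor",
]

# FWHM -> sigma conversion constant, 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class SubjectMatrix:
    """Subjects x in-mask-voxels data matrix with its voxel/grid map.

    Attributes
    ----------
    values : ndarray, shape (n_subjects, V)
        One row per subject; V = number of nonzero mask voxels.
    voxel_index_map : ndarray of int, shape (V, 3)
        Grid coordinate (i, j, k) of each column, in x-fastest
        (Fortran) scan order over the mask.
    subject_ids : list of str
    labels : DataFrame
        Per-row metadata (cohort, split, ...), index-aligned with rows.
    mask : Volume
        The binary mask defining the columns (carries grid geometry).
    """

    values: np.ndarray
    voxel_index_map: np.ndarray
    subject_ids: list
    labels: pd.DataFrame
    mask: Volume

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def row_to_volume(self, i: int) -> Volume:
        """Un-vectorize row *i* back onto the mask grid (off-mask = 0)."""
        return vector_to_volume(self.values[i], self.voxel_index_map, self.mask)

    def subset(self, rows) -> "SubjectMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        return SubjectMatrix(
            values=self.values[rows],
            voxel_index_map=self.voxel_index_map,
            subject_ids=[self.subject_ids[i] for i in rows],
            labels=self.labels.iloc[rows].reset_index(drop=True),
            mask=self.mask,
        )


def mask_scan_order(mask_data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flat (Fortran-order) indices and (i,j,k) coordinates of mask voxels."""
    binary = mask_data > 0.5
    flat = np.flatnonzero(binary.ravel(order="F"))
    ijk = np.column_stack(np.unravel_index(flat, binary.shape, order="F"))
    return flat, ijk


def vector_to_volume(vec: np.ndarray, voxel_index_map: np.ndarray, mask: Volume) -> Volume:
    out = np.zeros(mask.shape)
    out[tuple(voxel_index_map.T)] = vec
    return mask.copy(data=out)


def resample_volume(vol: Volume, target_voxel_mm: float) -> Volume:
    """Trilinearly resample onto an isotropic grid covering the same extent.

    The origin (world coordinate of voxel (0,0,0)) is preserved; the new
    grid has round(n * voxel / target) voxels per axis.
    """
    if target_voxel_mm <= 0:
        raise ValueError("target voxel size must be positive")
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("cannot resample a volume with non-finite values")
    new_shape = tuple(
        max(1, int(round(n * v / target_voxel_mm)))
        for n, v in zip(vol.shape, vol.voxel_size_mm)
    )
    if new_shape == vol.shape and all(
        abs(v - target_voxel_mm) < 1e-12 for v in vol.voxel_size_mm
    ):
        return vol.copy()
    # new voxel centers in source index units: i_new * target / voxel_src
    grids = [
        np.arange(n_new) * target_voxel_mm / v_src
        for n_new, v_src in zip(new_shape, vol.voxel_size_mm)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(
        vol.data, np.stack(coords), order=1, mode="nearest"
    )
    return Volume(
        data=out,
        voxel_size_mm=(target_voxel_mm,) * 3,
        origin_mm=vol.origin_mm,
    )


def smooth_volume(vol: Volume, fwhm_mm: float) -> Volume:
    """Gaussian-smooth with an isotropic kernel of the given FWHM (mm).

    sigma per axis (in voxels) is fwhm / (2*sqrt(2 ln 2)) / voxel_size.
    Boundary handling is constant extension (nearest), so constant
    volumes are preserved exactly.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return vol.copy()
    sigma_vox = [fwhm_mm / FWHM_TO_SIGMA / v for v in vol.voxel_size_mm]
    out = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="nearest")
    return vol.copy(data=out)


def intensity_normalize(vol: Volume) -> Volume:
    """Divide by the mean of the top-20% voxels above one-eighth of the mean.

    Eligibility is strict (value > mean/8, mean over the whole volume);
    the reference set is the ceil(0.2*m) largest eligible values (m = the
    eligible count, minimum one value). The result is invariant to a
    positive rescaling of the input.
    """
    data = vol.data
    threshold = data.mean() / 8.0
    eligible = data[data > threshold]
    if eligible.size == 0:
        raise ValueError(
            "intensity normalization failed: no voxel exceeds one-eighth "
            "of the image mean (all-zero or degenerate image)"
        )
    n_top = max(1, int(np.ceil(0.2 * eligible.size)))
    top = np.sort(eligible)[-n_top:]
    reference = float(top.mean())
    if reference <= 0:
        raise ValueError("intensity normalization reference is nonpositive")
    return vol.copy(data=data / reference)


def build_subject_matrix(
    volumes: list[Volume],
    mask: Volume,
    sheet: pd.DataFrame,
    volume_ids: list | None = None,
) -> SubjectMatrix:
    """Vectorize masked volumes into a subjects x voxels matrix.

    Rows follow the sheet's row order; columns are the nonzero mask
    voxels in x-fastest (Fortran) scan order. The sheet must have a
    ``subject_id`` column; ``volume_ids`` gives the subject id of each
    volume (defaults to sheet order).
    """
    if volume_ids is None:
        volume_ids = list(sheet["subject_id"])
    if len(volume_ids) != len(volumes):
        raise ValueError("volume_ids and volumes length mismatch")
    by_id = dict(zip(volume_ids, volumes))
    flat, ijk = mask_scan_order(mask.data)
    if flat.size == 0:
        raise ValueError("mask has no nonzero voxels")
    rows = []
    for sid in sheet["subject_id"]:
        if sid not in by_id:
            raise ValueError(f"subject {sid!r} in sheet has no volume")
        vol = by_id[sid]
        if not vol.same_grid(mask):
            raise ValueError(
                f"subject {sid!r}: volume grid {vol.shape}/{vol.voxel_size_mm} "
                f"does not match mask grid {mask.shape}/{mask.voxel_size_mm}"
            )
        rows.append(vol.data.ravel(order="F")[flat])
    return SubjectMatrix(
        values=np.asarray(rows),
        voxel_index_map=ijk,
        subject_ids=list(sheet["subject_id"]),
        labels=sheet.reset_index(drop=True).copy(),
        mask=mask,
    )


class PETPreprocessor(BaseEstimator, TransformerMixin):
    """Stateless transformer applying resample -> smooth -> normalize.

    Parameters
    ----------
    target_voxel_mm : float, default 2.0
        Isotropic voxel size after resampling.
    fwhm_mm : float, default 8.0
        Smoothing kernel FWHM in mm.
    """

    # the order of these stage names is asserted by a pipeline property test
    STAGES = ("resample", "smooth", "intensity_normalize")

    def __init__(self, target_voxel_mm: float = 2.0, fwhm_mm: float = 8.0):
        self.target_voxel_mm = target_voxel_mm
        self.fwhm_mm = fwhm_mm

    def fit(self, X=None, y=None):
        return self

    def transform_volume(self, vol: Volume) -> Volume:
        vol = resample_volume(vol, self.target_voxel_mm)
        vol = smooth_volume(vol, self.fwhm_mm)
        return intensity_normalize(vol)

    def transform(self, X):
        return [self.transform_volume(v) for v in X]
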