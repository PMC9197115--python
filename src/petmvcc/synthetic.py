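"""Seeded synthetic FDG-PET phantom cohorts with known ground truth.

Each phantom subject image is a constant positive baseline plus a linear
mixture of shared spatial sources (smooth Gaussian "disease" blobs at
configurable ROIs plus smooth random confound fields) plus i.i.d. voxel
noise, clipped at zero to respect PET nonnegativity. Disease-source
loadings are drawn per cohort: completely-detectable (CD) patients carry
the strongest mean loading, non-CD patients the same patterns at reduced
amplitude, and healthy participants a zero mean. This mirrors a
cross-decoding study design: the training split holds the CD patients
and half of the healthy participants, the testing split the non-CD
patients and the other half.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import FWHM_TO_SIGMA, mask_scan_order
from .volume import Volume

__all__ = ["PhantomConfig", "GroundTruth", "make_ground_truth", "sample_cohort", "write_fixture"]

DEFAULT_ROI_SPECS = (
    # (center mm (x, y, z), radius mm, sign): two medial-temporal-like and
    # two basal-ganglia-like hypermetabolic blobs
    ((-24.0, -8.0, -16.0), 8.0, +1),
    ((24.0, -8.0, -16.0), 8.0, +1),
    ((-14.0, 6.0, 0.0), 7.0, +1),
    ((14.0, 6.0, 0.0), 7.0, +1),
)


@dataclass
class PhantomConfig:
    """Generator settings; defaults define the package's study conditions."""

    grid_shape: tuple = (40, 48, 40)
    voxel_size_mm: float = 2.0
    roi_specs: tuple = DEFAULT_ROI_SPECS
    n_confound_sources: int = 6
    noise_sd: float = 0.5
    loading_means: dict = field(
        default_factory=lambda: {"CD": 0.8, "nonCD": 0.55, "healthy": 0.0}
    )
    loading_sd: float = 0.25
    confound_loading_sd: float = 1.0
    cohort_sizes: tuple = (17, 16, 17, 16)  # (n_CD, n_nonCD, n_healthy_train, n_healthy_test)
    baseline: float = 100.0
    mask_semiaxes_frac: float = 0.9  # ellipsoid semi-axes as fraction of half-extent
    ventricle_radius_mm: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for (_c, r, _s) in self.roi_specs):
            raise ValueError("all ROI radii must be positive")
        means = self.loading_means
        if any(n < 2 for n in self.cohort_sizes):
            raise ValueError("all cohort sizes must be >= 2")
        if self.baseline <= 0:
            raise ValueError("baseline intensity must be positive (PET nonnegativity)")
        if not (means["CD"] >= means["nonCD"] >= means["healthy"]):
            raise ValueError(
                "expected loading_means ordered CD >= nonCD >= healthy"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["cohort_sizes"] = list(self.cohort_sizes)
        d["roi_specs"] = [
            [list(c), r, s] for (c, r, s) in self.roi_specs
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["cohort_sizes"] = tuple(d["cohort_sizes"])
        d["roi_specs"] = tuple(
            (tuple(c), float(r), int(s)) for (c, r, s) in d["roi_specs"]
        )
        return cls(**d)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "PhantomConfig":
        """Reduced-scale preset (smaller grid/ROIs) for quick experiments."""
        kw = dict(
            grid_shape=(24, 28, 24),
            roi_specs=(
                ((-12.0, -4.0, -8.0), 6.0, +1),
                ((12.0, -4.0, -8.0), 6.0, +1),
                ((-8.0, 4.0, 0.0), 5.0, +1),
                ((8.0, 4.0, 0.0), 5.0, +1),
            ),
            n_confound_sources=4,
            cohort_sizes=(10, 10, 10, 10),
            seed=seed,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def origin_mm(self) -> tuple:
        # grid centered on the world origin
        return tuple(
            -(n - 1) / 2.0 * self.voxel_size_mm for n in self.grid_shape
        )

    @property
    def n_disease_sources(self) -> int:
        return len(self.roi_specs)

    @property
    def n_sources(self) -> int:
        return self.n_disease_sources + self.n_confound_sources


@dataclass
class GroundTruth:
    """Shared sources and geometry; filled with loadings by sample_cohort."""

    source_maps: np.ndarray  # (n_sources, V) standardized over mask voxels
    mask: Volume
    voxel_index_map: np.ndarray  # (V, 3)
    config: PhantomConfig
    mixing_coeffs: np.ndarray | None = None  # (n_subjects, n_sources)
    cohort_labels: list | None = None

    def source_volume(self, s: int) -> Volume:
        out = np.zeros(self.mask.shape)
        out[tuple(self.voxel_index_map.T)] = self.source_maps[s]
        return self.mask.copy(data=out)


def _world_grids(config: PhantomConfig):
    origin = config.origin_mm
    return [
        origin[ax] + np.arange(config.grid_shape[ax]) * config.voxel_size_mm
        for ax in range(3)
    ]


def _make_mask(config: PhantomConfig) -> Volume:
    gx, gy, gz = _world_grids(config)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    half_extent = [n * config.voxel_size_mm / 2.0 for n in config.grid_shape]
    semi = [config.mask_semiaxes_frac * h for h in half_extent]
    ellipsoid = (X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2 <= 1.0
    ventricle = X**2 + Y**2 + Z**2 <= config.ventricle_radius_mm**2
    mask = ellipsoid & ~ventricle
    return Volume(
        data=mask.astype(np.float64),
        voxel_size_mm=(config.voxel_size_mm,) * 3,
        origin_mm=config.origin_mm,
    )


def _standardize_over_mask(field_3d: np.ndarray, flat: np.ndarray) -> np.ndarray:
    vals = field_3d.ravel(order="F")[flat]
    sd = vals.std()
    if sd == 0:
        raise ValueError("degenerate source field with zero variance over the mask")
    return (vals - vals.mean()) / sd


def make_ground_truth(config: PhantomConfig) -> GroundTruth:
    """Build the mask and the standardized disease + confound source maps."""
    mask = _make_mask(config)
    flat, ijk = mask_scan_order(mask.data)
    gx, gy, gz = _world_grids(config)
    X, Y, Z = np.meshgrid(gx, gy, gz, indexing="ij")
    sources = []
    for i, (center, radius, sign) in enumerate(config.roi_specs):
        # center must fall on an in-mask voxel
        idx = tuple(
            int(round((center[ax] - config.origin_mm[ax]) / config.voxel_size_mm))
            for ax in range(3)
        )
        if (
            any(j < 0 or j >= n for j, n in zip(idx, config.grid_shape))
            or mask.data[idx] == 0
        ):
            raise ValueError(f"ROI {i} at {center} mm lies outside the mask")
        # isotropic Gaussian blob, FWHM = radius, truncated at 3 sigma
        sigma = radius / FWHM_TO_SIGMA
        d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        blob = np.exp(-0.5 * d2 / sigma**2)
        blob[d2 > (3.0 * sigma) ** 2] = 0.0
        sources.append(sign * _standardize_over_mask(blob, flat))
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0]).generate_state(1)[0]
    )
    from scipy import ndimage  # local import to keep module load light

    sigma_vox = 8.0 / FWHM_TO_SIGMA / config.voxel_size_mm
    for _ in range(config.n_confound_sources):
        white = rng.standard_normal(config.grid_shape)
        smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="nearest")
        sources.append(_standardize_over_mask(smooth, flat))
    source_maps = np.asarray(sources)
    # sanity: full column rank of the source matrix over voxels
    if np.linalg.matrix_rank(source_maps) < source_maps.shape[0]:
        raise ValueError("source maps are rank deficient")
    return GroundTruth(
        source_maps=source_maps,
        mask=mask,
        voxel_index_map=ijk,
        config=config,
    )


def sample_cohort(
    gt: GroundTruth, config: PhantomConfig | None = None
) -> tuple[list[Volume], pd.DataFrame]:
    """Draw per-subject loadings and synthesize the four phantom cohorts.

    Returns one volume per subject plus a participant sheet (subject_id,
    cohort, split, age, sex). CD patients and the first healthy group form
    the training split; non-CD patients and the second healthy group form
    the testing split. Drawn loadings are stored on ``gt.mixing_coeffs``.
    """
    config = config or gt.config
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1]).generate_state(1)[0]
    )
    n_cd, n_noncd, n_htrain, n_htest = config.cohort_sizes
    plan = (
        [("CD", "train")] * n_cd
        + [("healthy", "train")] * n_htrain
        + [("nonCD", "test")] * n_noncd
        + [("healthy", "test")] * n_htest
    )
    n_subjects = len(plan)
    n_dis, n_conf = config.n_disease_sources, config.n_confound_sources
    loadings = np.empty((n_subjects, n_dis + n_conf))
    rows = []
    flat, _ = mask_scan_order(gt.mask.data)
    mask_ind = gt.mask.data > 0.5
    volumes = []
    for i, (cohort, split) in enumerate(plan):
        mu = config.loading_means[cohort]
        loadings[i, :n_dis] = rng.normal(mu, config.loading_sd, size=n_dis)
        loadings[i, n_dis:] = rng.normal(0.0, config.confound_loading_sd, size=n_conf)
        signal = loadings[i] @ gt.source_maps
        buf = np.zeros(int(np.prod(gt.mask.shape)))
        buf[flat] = (
            config.baseline
            + signal
            + config.noise_sd * rng.standard_normal(flat.size)
        )
        data = buf.reshape(gt.mask.shape, order="F")
        data[~mask_ind] = 0.0
        np.clip(data, 0.0, None, out=data)
        volumes.append(gt.mask.copy(data=data))
        age_mu, age_sd = (58.0, 12.0) if cohort != "healthy" else (55.0, 8.0)
        rows.append(
            {
                "subject_id": f"sub-{i + 1:03d}",
                "cohort": cohort,
                "split": split,
                "age": float(np.clip(rng.normal(age_mu, age_sd), 30, 80).round(1)),
                "sex": "M" if rng.random() < 0.6 else "F",
            }
        )
    gt.mixing_coeffs = loadings
    gt.cohort_labels = [c for c, _ in plan]
    return volumes, pd.DataFrame(rows)


def write_fixture(
    gt: GroundTruth, volumes: list[Volume], sheet: pd.DataFrame, directory
) -> dict:
    """Write NIfTI volumes, the mask, the sheet CSV and a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    gt.mask.save(directory / "mask.nii.gz")
    for sid, vol in zip(sheet["subject_id"], volumes):
        vol.save(directory / f"{sid}.nii.gz")
    sheet.to_csv(directory / "sheet.csv", index=False)
    manifest = {
        "seed": int(gt.config.seed),
        "config": gt.config.to_dict(),
        "config_sha256": gt.config.digest(),
        "n_subjects": int(len(volumes)),
        "mask_voxels": int((gt.mask.data > 0.5).sum()),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def generate(config: PhantomConfig):
    """Convenience: ground truth + cohort volumes + sheet in one call."""
    gt = make_ground_truth(config)
    volumes, sheet = sample_cohort(gt, config)
    return gt, volumes, sheet
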