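"""End-to-end orchestration: simulate/load -> preprocess -> ICA -> classify -> maps -> stats.

The cross-classification firewall is enforced structurally: the ICA
model, the coefficient normalization statistics and the classifier are
fit exclusively on split == "train" rows; test rows are only projected,
rescaled with training statistics, and scored.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, cohortstats, maps
from .ica import CoefficientScaler, ReliableSpatialICA
from .preprocess import PETPreprocessor, build_subject_matrix, vector_to_volume
from .synthetic import PhantomConfig, generate
from .volume import Volume

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_inputs", "stage_seed"]

PATIENT_COHORTS = ("CD", "nonCD")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed: CRC32 of the stage name mixed with the master."""
    return int(
        np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults are the method's standard settings."""

    # inputs: either a directory of NIfTI volumes + mask + sheet, or a phantom
    volumes_dir: str | None = None
    mask_path: str | None = None
    sheet_path: str | None = None
    phantom: PhantomConfig | None = None
    output_dir: str | None = None
    # preprocessing
    target_voxel_mm: float = 2.0
    fwhm_mm: float = 8.0
    # ICA
    n_components: int | None = None
    n_runs: int = 200
    seed: int = 0
    # classifier
    lambda_low_exp: int = -10
    lambda_high_exp: int = 10
    # maps
    z_threshold: float = 2.58
    min_extent: int = 50
    top_fraction: float = 0.05
    connectivity: int = 18
    min_separation_mm: float = 8.0
    # stats: list of (variable, kind) comparisons run between patient cohorts
    stat_variables: tuple = (("age", "continuous"), ("sex", "categorical"))

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.phantom is not None:
            d["phantom"] = self.phantom.to_dict()
        d["stat_variables"] = [list(v) for v in self.stat_variables]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("phantom"):
            d["phantom"] = PhantomConfig.from_dict(d["phantom"])
        if "stat_variables" in d:
            d["stat_variables"] = tuple(tuple(v) for v in d["stat_variables"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class RunReport:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    classification: classify.ClassificationReport | None = None
    train_classification: classify.ClassificationReport | None = None
    cv_result: classify.CVResult | None = None
    cluster_tables: list = field(default_factory=list)
    demographics: pd.DataFrame | None = None
    selected_components: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    checksums: dict = field(default_factory=dict)

    def summary(self) -> dict:
        rep = self.classification
        return {
            "seed": self.seed,
            "selected_lambda": None if self.cv_result is None else self.cv_result.selected_lambda,
            "test_accuracy": None if rep is None else rep.accuracy,
            "test_sensitivity": None if rep is None else rep.sensitivity,
            "test_specificity": None if rep is None else rep.specificity,
            "test_auc": None if rep is None else rep.auc,
            "selected_components": self.selected_components,
            "stages": self.stages,
            "warnings": self.warnings,
        }


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def _load_inputs(config: PipelineConfig):
    if config.phantom is not None:
        phantom = config.phantom
        _gt, volumes, sheet = generate(phantom)
        mask = _gt.mask
        return volumes, mask, sheet
    if not (config.volumes_dir and config.mask_path and config.sheet_path):
        raise ValueError("either a phantom config or volume/mask/sheet paths are required")
    sheet = pd.read_csv(config.sheet_path)
    mask = Volume.load(config.mask_path)
    volumes = [
        Volume.load(Path(config.volumes_dir) / f"{sid}.nii.gz")
        for sid in sheet["subject_id"]
    ]
    return volumes, mask, sheet


def validate_inputs(config: PipelineConfig) -> dict:
    """Collect (not fail-fast) structural problems with the configured inputs."""
    report = {"errors": [], "warnings": [], "settings": config.to_dict()}
    try:
        if config.phantom is not None:
            volumes, mask, sheet = _load_inputs(config)
        else:
            sheet = pd.read_csv(config.sheet_path)
            mask = Volume.load(config.mask_path)
            volumes = []
            for sid in sheet["subject_id"]:
                p = Path(config.volumes_dir) / f"{sid}.nii.gz"
                if not p.exists():
                    report["errors"].append(f"subject {sid!r}: missing volume {p}")
                else:
                    volumes.append(Volume.load(p))
    except Exception as exc:  # noqa: BLE001 - surfaced, not swallowed
        report["errors"].append(str(exc))
        return report
    if (mask.data > 0.5).sum() == 0:
        report["errors"].append("mask has 0 nonzero voxels (fatal)")
    sizes = {tuple(np.round(v.voxel_size_mm, 6)) for v in volumes}
    if len(sizes) > 1:
        report["errors"].append(f"mixed voxel sizes across volumes: {sorted(sizes)}")
    for col in ("subject_id", "cohort", "split"):
        if col not in sheet.columns:
            report["errors"].append(f"sheet is missing required column {col!r}")
    if "split" in sheet.columns and "cohort" in sheet.columns:
        train = sheet[sheet["split"] == "train"]
        y = train["cohort"].isin(PATIENT_COHORTS)
        if y.nunique() < 2:
            report["errors"].append("training split does not contain both classes")
    return report


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full cross-classification pipeline from a single config."""
    report = RunReport(config=config.to_dict(), seed=config.seed)

    volumes, mask, sheet = _load_inputs(config)
    report.stages["load"] = {"n_subjects": len(volumes)}

    pre = PETPreprocessor(target_voxel_mm=config.target_voxel_mm, fwhm_mm=config.fwhm_mm)
    processed = pre.transform(volumes)
    mask_res = mask
    if any(abs(v - config.target_voxel_mm) > 1e-9 for v in mask.voxel_size_mm):
        from .preprocess import resample_volume

        mask_res = resample_volume(mask, config.target_voxel_mm)
        mask_res = mask_res.copy(data=(mask_res.data > 0.5).astype(float))
    sm = build_subject_matrix(processed, mask_res, sheet)
    report.stages["preprocess"] = {"n_voxels": sm.n_voxels}

    is_train = (sheet["split"] == "train").to_numpy()
    is_test = (sheet["split"] == "test").to_numpy()
    X_train = sm.subset(is_train)
    X_test = sm.subset(is_test)
    y_train = X_train.labels["cohort"].isin(PATIENT_COHORTS).to_numpy().astype(int)
    y_test = X_test.labels["cohort"].isin(PATIENT_COHORTS).to_numpy().astype(int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training split must contain both classes")

    n_comp = config.n_components
    ica = ReliableSpatialICA(
        n_components=n_comp,
        n_runs=config.n_runs,
        random_state=stage_seed(config.seed, "ica"),
    ).fit(X_train)
    low_quality = np.flatnonzero(ica.cluster_quality_ < 0.8)
    if low_quality.size:
        report.warnings.append(
            f"low ICA cluster quality (<0.8) for components {low_quality.tolist()}"
        )
    A_train = ica.transform(X_train, role="training")
    A_test = ica.transform(X_test, role="testing")
    scaler = CoefficientScaler().fit(A_train)
    A_train_n = scaler.transform(A_train)
    A_test_n = scaler.transform(A_test)
    report.stages["ica"] = {
        "n_components": int(ica.n_components_),
        "mean_cluster_quality": float(ica.cluster_quality_.mean()),
    }
    report.checksums["ica_components"] = _checksum(ica.components_)
    report.checksums["coefficient_norm"] = _checksum(
        np.concatenate([scaler.mean_, scaler.sd_])
    )

    grid = 2.0 ** np.arange(config.lambda_low_exp, config.lambda_high_exp + 1)
    clf = classify.MVCCLogisticRegression(lambda_grid=grid).fit(A_train_n, y_train)
    report.cv_result = clf.cv_result_
    report.train_classification = clf.report(A_train_n, y_train)
    report.classification = clf.report(A_test_n, y_test)
    report.stages["classify"] = {"selected_lambda": clf.lambda_}
    report.checksums["classifier"] = _checksum(
        np.concatenate([clf.coef_, [clf.intercept_]])
    )

    selected, ranking = maps.rank_weights(clf.coef_, config.top_fraction)
    report.selected_components = [int(c) for c in selected]
    report.stages["maps"] = {"ranking": [int(c) for c in ranking]}
    for comp in selected:
        comp_vol = vector_to_volume(
            ica.components_[comp], sm.voxel_index_map, mask_res
        )
        corrected = maps.sign_correct(comp_vol.data, clf.coef_[comp])
        zm = maps.zscore_map(
            corrected, mask_res, component_id=int(comp),
            weight_sign=int(np.sign(clf.coef_[comp])),
        )
        table = maps.threshold_clusters(
            zm, config.z_threshold, config.min_extent, config.connectivity
        )
        table = maps.find_peaks(zm, table, config.min_separation_mm)
        report.cluster_tables.append(table)

    demo_rows = []
    pat = sheet[sheet["cohort"].isin(PATIENT_COHORTS)]
    if pat["cohort"].nunique() == 2:
        for var, kind in config.stat_variables:
            if var not in sheet.columns:
                continue
            pos = None
            if kind == "categorical" and var == "sex":
                pos = "M"
            res = cohortstats.compare_cohorts(
                pat, var, kind, group_col="cohort",
                groups=("CD", "nonCD"), positive_value=pos,
            )
            demo_rows.append(
                {"variable": var, "test": res.test,
                 "statistic": res.statistic, "df": res.df, "p": res.p_two_sided}
            )
    report.demographics = pd.DataFrame(demo_rows)
    report.stages["stats"] = {"n_comparisons": len(demo_rows)}

    if config.output_dir:
        _write_outputs(config, report, ica, A_train_n, A_test_n, mask_res, sm)
    return report


def _write_outputs(config, report, ica, A_train_n, A_test_n, mask_res, sm):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2, default=str)
    with open(out / "classification_report.json", "w") as fh:
        json.dump(report.classification.to_dict(), fh, indent=2)
    for role, A in (("train", A_train_n), ("test", A_test_n)):
        cols = [f"IC{j + 1}" for j in range(A.A.shape[1])]
        pd.DataFrame(A.A, columns=cols, index=A.subject_ids).to_csv(
            out / f"coefficients_{role}.csv", index_label="subject_id"
        )
    for table in report.cluster_tables:
        table.to_frame().to_csv(
            out / f"clusters_IC{table.component_id + 1}.csv", index=False
        )
    if report.demographics is not None:
        report.demographics.to_csv(out / "demographics.csv", index=False)
    comp4d = np.zeros(mask_res.shape + (ica.components_.shape[0],))
    for j in range(ica.components_.shape[0]):
        comp4d[..., j] = vector_to_volume(
            ica.components_[j], sm.voxel_index_map, mask_res
        ).data
    import nibabel as nib

    nib.save(nib.Nifti1Image(comp4d, mask_res.affine), str(out / "components.nii.gz"))
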