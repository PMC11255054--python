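"""Cohort orchestration: NIfTI loading, configuration, and the full run.

``run_all`` ties the stages together: per-patient voxel extraction →
per-feature group statistics → univariate filtering / RFE / gradient
boosting — writing ``features.csv``, ``stats.csv``, ``whisker.csv`` and a
machine-readable ``report.json`` that echoes every parameter in effect.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import classify, features, stats
from .dsc import DscSeries
from .errors import (
    EmptyCandidateSet,
    FormatError,
    GridMismatch,
    ParameterError,
    PerfquantError,
)

log = logging.getLogger("perfquant")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    ``cohort_dir`` must contain ``patient_*/`` directories with
    ``dsc.nii.gz``, ``tumor_mask.nii.gz`` and ``nawm_mask.nii.gz`` plus a
    cohort-level ``truth.csv`` (columns ``patient_id``, ``label``).
    """

    cohort_dir: str
    out_dir: str
    seed: int
    te: float = 0.040
    tr: float | None = None  # None: read from the NIfTI header (pixdim[4])
    qc_depth_snr: float = 5.0
    min_baseline: int = 8
    k_sigma: float = 3.0
    n_folds: int = 10
    auc_min: float = 0.8
    p_max: float = 0.005
    n_features: int = 5
    rfe_inner_folds: int = 5
    bonferroni_m: int = stats.DEFAULT_BONFERRONI_M
    gbm: dict = field(default_factory=lambda: dict(classify.DEFAULT_GBM_PARAMS))

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if not (0.5 <= self.auc_min <= 1.0) or not (0.0 < self.p_max <= 1.0):
            raise ParameterError("filter thresholds out of documented range")
        if self.qc_depth_snr < 0 or self.n_features < 1:
            raise ParameterError("invalid QC/selection settings")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)


def load_patient(
    dsc_path: str | Path,
    tumor_path: str | Path,
    nawm_path: str | Path,
    te: float = 0.040,
    tr: float | None = None,
) -> tuple[DscSeries, np.ndarray, np.ndarray]:
    """Load one patient's 4D series and masks, validating the shared grid.

    The repetition time is taken from the series header (``pixdim[4]``)
    unless overridden; echo time is not stored in NIfTI and must come from
    configuration.
    """
    img = nib.load(str(dsc_path))
    if img.ndim != 4:
        raise FormatError(f"{dsc_path}: expected a 4D series, got {img.ndim}D")
    if tr is None:
        tr = float(img.header["pixdim"][4])
        if tr <= 0:
            raise FormatError(f"{dsc_path}: header pixdim[4] holds no TR; pass tr=")
    masks = []
    for path in (tumor_path, nawm_path):
        mimg = nib.load(str(path))
        if mimg.ndim != 3:
            raise FormatError(f"{path}: expected a 3D mask, got {mimg.ndim}D")
        if mimg.shape != img.shape[:3]:
            raise GridMismatch(
                f"{path}: mask shape {mimg.shape} vs series grid {img.shape[:3]}"
            )
        if not np.allclose(mimg.affine, img.affine, atol=1e-4):
            raise GridMismatch(f"{path}: affine differs from the series affine")
        masks.append(np.asarray(mimg.dataobj).astype(np.uint8))
    series = DscSeries(
        data=np.asarray(img.dataobj, dtype=float), tr=tr, te=te, affine=img.affine
    )
    return series, masks[0], masks[1]


def extract_cohort_features(config: RunConfig) -> pd.DataFrame:
    """Per-patient feature vectors for every patient directory in the cohort."""
    cohort_dir = Path(config.cohort_dir)
    truth = pd.read_csv(cohort_dir / "truth.csv").set_index("patient_id")
    rows = []
    for pdir in sorted(cohort_dir.glob("patient_*")):
        pid = pdir.name
        try:
            series, tumor_mask, nawm_mask = load_patient(
                pdir / "dsc.nii.gz", pdir / "tumor_mask.nii.gz",
                pdir / "nawm_mask.nii.gz", te=config.te, tr=config.tr,
            )
            vec, _ = features.patient_features(
                series, tumor_mask, nawm_mask,
                qc_depth_snr=config.qc_depth_snr,
                min_baseline=config.min_baseline, k_sigma=config.k_sigma,
            )
        except PerfquantError as exc:
            raise type(exc)(f"[extract/{pid}] {exc}") from exc
        rows.append({"patient_id": pid, "label": truth.loc[pid, "label"], **vec})
        log.info("extracted %s (%d ok voxels)", pid, vec["n_voxels_ok"])
    return pd.DataFrame(rows)


def simulate_and_extract(
    preset,
    n_tumors: int,
    n_voxels: int = 300,
    seed: int = 0,
    acq=None,
    shape: tuple[int, int, int] = (22, 22, 10),
    n_nawm: int = 50,
) -> pd.DataFrame:
    """Simulate ``n_tumors`` patients of one class and run the full pipeline.

    Each patient is forward-simulated (voxel curves embedded in a volume with
    tumor and NAWM masks), then analyzed end to end: bolus detection, ΔR2*
    conversion, BSW leakage fit against the NAWM reference, corrected CBV,
    NAWM normalization, early PSR, and the 44 histogram features.  Returns
    one row per patient: label, the drawn ground-truth tumor means, and the
    recovered features.  Deterministic given the seed.
    """
    from . import synthetic

    acq = acq or synthetic.AcquisitionParams()
    template = synthetic.make_bolus_template(acq)
    rows = []
    for ss in np.random.SeedSequence(seed).spawn(n_tumors):
        rng = np.random.default_rng(ss)
        tumor = synthetic.simulate_tumor(
            preset, n_voxels, acq, rng, n_nawm=n_nawm, template=template
        )
        data, tmask, nmask = synthetic.assemble_patient(tumor, shape, rng)
        series = DscSeries(data, acq.tr, acq.te)
        vec, _ = features.patient_features(series, tmask, nmask)
        rows.append({
            "label": tumor.label,
            "truth_mean_cbv": tumor.mean_cbv_ratio,
            "truth_mean_psr": tumor.mean_psr,
            **vec,
        })
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Execute extraction → statistics → classification and write reports.

    Returns the report dict (also written to ``report.json``).  Every
    numeric in the report traces to a config value or a computed quantity.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    try:
        log.info("run_all config: %s", dataclasses.asdict(config))
        cohort = extract_cohort_features(config)
        cohort.to_csv(out / "features.csv", index=False)

        try:
            stat_rows = stats.feature_stat_table(
                cohort, features.FEATURE_COLUMNS, k=config.n_folds,
                seed=config.seed, bonferroni_m=config.bonferroni_m,
            )
        except PerfquantError as exc:
            raise type(exc)(f"[group_stats] {exc}") from exc
        stat_rows.to_csv(out / "stats.csv", index=False)
        whisk = classify._cohort_whiskers(
            cohort, list(features.FEATURE_COLUMNS), "label"
        )
        whisk.to_csv(out / "whisker.csv", index=False)

        # redundancy check between the two metrics: Spearman rho for each
        # paired summary (nrCBV_x vs PSR_x) — low correlations mean the
        # metrics carry complementary information worth combining
        spearman = {}
        for summary in features.SUMMARIES:
            pair = cohort[[f"nrCBV_{summary}", f"PSR_{summary}"]]
            rho, pv = stats.spearman_matrix(pair)
            spearman[summary] = {
                "rho": float(rho.iloc[0, 1]), "p": float(pv.iloc[0, 1])
            }

        report: dict = {
            "config": dataclasses.asdict(config),
            "n_patients": int(len(cohort)),
            "n_features": len(features.FEATURE_COLUMNS),
            "spearman_nrcbv_vs_psr": spearman,
        }
        clf = classify.AucFilteredBoostingClassifier(
            auc_min=config.auc_min, p_max=config.p_max,
            n_features=config.n_features, n_folds=config.n_folds,
            rfe_inner_folds=config.rfe_inner_folds,
            random_state=config.seed, **config.gbm,
        )
        try:
            clf.fit(cohort[list(features.FEATURE_COLUMNS)], cohort.label,
                    stat_rows=stat_rows)
        except EmptyCandidateSet as exc:
            log.warning("classifier halted: %s", exc)
            report["classifier"] = {"halted": str(exc)}
        except PerfquantError as exc:
            raise type(exc)(f"[classifier] {exc}") from exc
        else:
            report["classifier"] = clf.report_.to_dict()
        (out / "report.json").write_text(json.dumps(report, indent=2))
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
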