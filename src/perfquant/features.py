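"""Whole-tumor feature extraction.

Applies the per-curve analytics of :mod:`perfquant.dsc` to every voxel in a
3D tumor mask, normalizes leakage-corrected CBV to a normal-appearing
white-matter (NAWM) reference, applies voxel quality control, and summarizes
each tumor as 44 histogram features: mean, min, max and the percentiles
p5, p10, …, p95 of nrCBV and PSR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dsc
from .errors import (
    CurveTooShort,
    InsufficientBaseline,
    NoBolusDetected,
    QCReject,
    ReferenceUnavailable,
    ShapeError,
    TooFewVoxels,
)

PERCENTILES: tuple[int, ...] = tuple(range(5, 100, 5))
SUMMARIES: tuple[str, ...] = ("mean", "min", "max") + tuple(f"p{q}" for q in PERCENTILES)
METRICS: tuple[str, ...] = ("nrCBV", "PSR")
FEATURE_COLUMNS: tuple[str, ...] = tuple(
    f"{m}_{s}" for m in METRICS for s in SUMMARIES
)
MIN_OK_VOXELS = 10

QC_OK = "ok"
QC_NO_BOLUS = "no_bolus"
QC_LOW_DEPTH = "low_depth"
QC_SHORT_CURVE = "short_curve"


def _mask_indices(mask: np.ndarray) -> np.ndarray:
    return np.column_stack(np.nonzero(np.asarray(mask) != 0))


def nawm_reference(
    series: dsc.DscSeries, nawm_mask: np.ndarray, **marker_kwargs
) -> tuple[float, dsc.ConcCurve]:
    """Reference quantities from the NAWM mask.

    Returns the voxel-mean ΔR2* curve (the BSW reference R̄) and the scalar
    reference rCBV — the mean, over NAWM voxels, of the uncorrected
    trapezoidal area from each voxel's bolus arrival onward.
    """
    idx = _mask_indices(nawm_mask)
    if idx.shape[0] == 0:
        raise ReferenceUnavailable("NAWM mask is empty")
    if nawm_mask.shape != series.data.shape[:3]:
        raise ShapeError(
            f"NAWM mask {nawm_mask.shape} does not match series grid {series.data.shape[:3]}"
        )
    concs, areas = [], []
    for x, y, z in idx:
        curve = series.curve((x, y, z))
        try:
            markers = dsc.detect_bolus_markers(curve, **marker_kwargs)
        except (NoBolusDetected, InsufficientBaseline, CurveTooShort):
            continue
        conc = dsc.signal_to_delta_r2star(curve, markers)
        concs.append(conc.delta_r2star)
        areas.append(dsc.uncorrected_cbv(conc, markers))
    if not concs:
        raise ReferenceUnavailable("every NAWM voxel failed bolus detection")
    ref = dsc.ConcCurve(np.mean(concs, axis=0), dt=series.tr)
    return float(np.mean(areas)), ref


def extract_voxel_metrics(
    series: dsc.DscSeries,
    tumor_mask: np.ndarray,
    nawm_mask: np.ndarray,
    qc_depth_snr: float = 5.0,
    **marker_kwargs,
) -> pd.DataFrame:
    """Per-voxel leakage-corrected nrCBV and PSR for one tumor.

    Each tumor voxel runs the full curve pipeline: bolus-marker detection,
    ΔR2* conversion, BSW fit against the NAWM reference, corrected CBV and
    early PSR.  A voxel is rejected (``low_depth``) when its bolus depth
    (s0 − S_min) is below ``qc_depth_snr`` baseline noise SDs; detection
    failures are flagged ``no_bolus``/``short_curve``.  Rejected voxels
    carry NaN metrics.
    """
    if tumor_mask.shape != series.data.shape[:3]:
        raise ShapeError(
            f"tumor mask {tumor_mask.shape} does not match series grid {series.data.shape[:3]}"
        )
    idx = _mask_indices(tumor_mask)
    if idx.shape[0] == 0:
        raise ShapeError("tumor mask is empty")
    ref_rcbv, ref_conc = nawm_reference(series, nawm_mask, **marker_kwargs)
    rows = []
    for x, y, z in idx:
        row = {
            "x": int(x), "y": int(y), "z": int(z), "qc_flag": QC_OK,
            "rcbv_corrected": np.nan, "nrcbv": np.nan, "psr": np.nan,
            "k1": np.nan, "k2": np.nan,
        }
        curve = series.curve((x, y, z))
        try:
            markers = dsc.detect_bolus_markers(curve, **marker_kwargs)
            depth = markers.s0 - float(curve.values[markers.t_min])
            if markers.baseline_sd > 0 and depth / markers.baseline_sd < qc_depth_snr:
                raise QCReject("bolus depth below the QC noise floor")
            conc = dsc.signal_to_delta_r2star(curve, markers)
            fit = dsc.fit_bsw(conc, ref_conc, markers)
            rcbv = dsc.corrected_cbv(conc, fit, ref_conc, markers)
            psr = dsc.compute_psr(curve, markers)
        except (NoBolusDetected, InsufficientBaseline):
            row["qc_flag"] = QC_NO_BOLUS
        except CurveTooShort:
            row["qc_flag"] = QC_SHORT_CURVE
        except QCReject:
            row["qc_flag"] = QC_LOW_DEPTH
        else:
            row.update(
                rcbv_corrected=rcbv, nrcbv=rcbv / ref_rcbv, psr=psr,
                k1=fit.k1, k2=fit.k2,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def feature_vector_from_values(
    nrcbv: np.ndarray, psr: np.ndarray
) -> dict[str, float]:
    """44 histogram features from paired per-voxel nrCBV and PSR values.

    Percentiles use linear interpolation between order statistics (the
    inclusive convention, numpy's default).
    """
    out: dict[str, float] = {}
    for name, vals in (("nrCBV", np.asarray(nrcbv, float)), ("PSR", np.asarray(psr, float))):
        if vals.size < MIN_OK_VOXELS:
            raise TooFewVoxels(f"{vals.size} voxels < required {MIN_OK_VOXELS}")
        out[f"{name}_mean"] = float(vals.mean())
        out[f"{name}_min"] = float(vals.min())
        out[f"{name}_max"] = float(vals.max())
        pct = np.percentile(vals, PERCENTILES)
        for q, v in zip(PERCENTILES, pct):
            out[f"{name}_p{q}"] = float(v)
    return out


def percentile_features(table: pd.DataFrame) -> pd.Series:
    """Per-tumor feature vector over quality-controlled voxels.

    Only ``qc_flag == "ok"`` voxels contribute.  Returns the 44 metric
    features plus the bookkeeping counts ``n_voxels_ok`` and
    ``n_voxels_rejected``.
    """
    ok = table[table.qc_flag == QC_OK]
    n_ok = len(ok)
    if n_ok < MIN_OK_VOXELS:
        raise TooFewVoxels(f"only {n_ok} qc-ok voxels (need >= {MIN_OK_VOXELS})")
    feats = feature_vector_from_values(ok.nrcbv.to_numpy(), ok.psr.to_numpy())
    feats["n_voxels_ok"] = n_ok
    feats["n_voxels_rejected"] = len(table) - n_ok
    return pd.Series(feats)


def patient_features(
    series: dsc.DscSeries,
    tumor_mask: np.ndarray,
    nawm_mask: np.ndarray,
    qc_depth_snr: float = 5.0,
    **marker_kwargs,
) -> tuple[pd.Series, pd.DataFrame]:
    """Convenience wrapper: voxel metrics table plus its feature vector."""
    table = extract_voxel_metrics(
        series, tumor_mask, nawm_mask, qc_depth_snr=qc_depth_snr, **marker_kwargs
    )
    return percentile_features(table), table
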