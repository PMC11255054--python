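"""Forward simulation of gradient-echo DSC time-intensity curves and cohorts.

The generator produces voxel-level curves with known ground truth so the
whole analysis chain (bolus detection → ΔR2* conversion → BSW leakage
correction → NAWM-normalized CBV → early PSR → histogram features →
statistics → classification) can be validated on a desk.

Signal model
------------
Monoexponential T2* signal equation with ΔR2* linear in contrast
concentration.  The reference (NAWM) relaxation curve is a gamma-variate
first pass plus recirculation and a plateau term::

    R_ref(t) = C(t) + q_n·∫₀ᵗC,          C = first pass + recirculation

and every voxel is built inside the model class the BSW leakage correction
fits (scaled reference plus a term along the running integral of the
reference)::

    R_v(t)   = cbv_ratio·R_ref(t−delay) + (q_v + leak_k2)·∫₀ᵗR_ref(τ−delay)dτ
    S(t)     = s0 · exp(−TE · R_v(t)) + ε,      ε ~ N(0, noise_sd²)

* ``C`` is a gamma-variate bolus (shape α = 3, scale ≈ 2 s → ~12 s first
  pass) plus a delayed (8·TR), broadened, 15%-amplitude recirculation gamma.
* ``q_v`` is the plateau coefficient, calibrated per voxel in closed form
  (inverting the exponential signal equation, iterated with the analysis
  first-pass-end rule) so that the measured early PSR equals ``psr_true`` in
  the noiseless leak-free limit; ``q_n`` plays the same role for NAWM.
* Because a leak-free voxel lies exactly in span{R_ref, ∫R_ref}, the BSW
  fit — and hence the NAWM-normalized corrected CBV round trip — is exact
  in the noiseless limit; ``cbv_ratio`` is, by construction, the voxel's
  blood-volume ratio relative to NAWM.
* ``leak_k2`` models T1-/T2*-dominant leakage of either sign along the BSW
  leakage basis (the method's own forward model); T1 shine-through is not
  modelled separately since grade 2-3 gliomas have a largely intact
  blood-brain barrier.  ``psr_true`` is the recovery of the leak-free twin;
  nonzero leakage shifts the measured PSR, as it does in vivo.

NAWM voxels are generated with ``cbv_ratio = 1`` and ``psr_true = 0.9``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import truncnorm

from .dsc import first_pass_end_index
from .errors import ParameterError

DISCARD_N = 3  # leading non-steady-state dynamics, held at s0
NAWM_CBV_RATIO = 1.0
NAWM_PSR = 0.9
CBV_TRUNC = (0.2, 8.0)  # population truncation for per-tumor mean CBV ratio
PSR_TRUNC = (0.05, 1.25)  # population truncation for PSR
VOXEL_PSR_MIN = 0.15  # voxel-level floor: below this the early-PSR operating
# definition degenerates (plateau indistinguishable from the signal minimum)
PSR_MAX = 1.3  # per-voxel hard ceiling (overshoot allowed)


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo DSC acquisition settings.

    Defaults follow a 1.5-3 T clinical protocol: TE 40 ms, TR 1.5 s,
    60 dynamics with a 12-point baseline, SNR s0/noise_sd = 50.
    """

    te: float = 0.040
    tr: float = 1.5
    n_dynamics: int = 60
    n_baseline: int = 12
    s0: float = 600.0
    noise_sd: float = 12.0

    def __post_init__(self) -> None:
        if self.te <= 0 or self.tr <= 0:
            raise ParameterError("te and tr must be positive")
        if self.n_dynamics < 30:
            raise ParameterError("n_dynamics must be >= 30")
        if not (8 <= self.n_baseline <= self.n_dynamics / 3):
            raise ParameterError("n_baseline must satisfy 8 <= n_baseline <= n_dynamics/3")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.s0 <= 0:
            raise ParameterError("s0 must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_dynamics) * self.tr

    @property
    def arrival_index(self) -> int:
        return DISCARD_N + self.n_baseline


@dataclass(frozen=True)
class VoxelTruth:
    """Ground truth for one simulated voxel."""

    cbv_ratio: float
    psr_true: float
    leak_k2: float = 0.0
    bolus_delay: float = 0.0

    def __post_init__(self) -> None:
        if self.cbv_ratio < 0:
            raise ParameterError("cbv_ratio must be >= 0")
        if not (0.0 <= self.psr_true <= PSR_MAX):
            raise ParameterError(f"psr_true must lie in [0, {PSR_MAX}]")
        if not np.isfinite(self.leak_k2):
            raise ParameterError("leak_k2 must be finite")


@dataclass(frozen=True)
class ClassPreset:
    """Population parameters of one tumor class.

    ``mean_nrcbv_mu/sd`` and ``psr_mu/sd`` describe the across-patient
    distribution of per-tumor mean CBV ratio and mean PSR;
    ``intra_tumor_cbv_cv`` is the within-tumor lognormal coefficient of
    variation, ``intra_tumor_psr_sd`` the within-tumor PSR spread.  A tumor
    is leaky with probability ``leak_prob``; its leakage coefficient is drawn
    N(0, leak_scale²) (1/s per unit integrated reference concentration).

    ``dispersion_jitter`` is the lognormal sigma of a per-tumor multiplier on
    both intra-tumor spreads: tumors differ in how heterogeneous they are,
    which (as in vivo) makes per-tumor extremes (min/max) far noisier
    discriminators than central percentiles.
    """

    label: str
    mean_nrcbv_mu: float
    mean_nrcbv_sd: float
    psr_mu: float
    psr_sd: float
    intra_tumor_cbv_cv: float = 0.53
    intra_tumor_psr_sd: float = 0.08
    dispersion_jitter: float = 0.4
    leak_prob: float = 0.3
    leak_scale: float = 0.005

    def __post_init__(self) -> None:
        if self.label not in ("astrocytoma", "oligodendroglioma"):
            raise ParameterError(f"unknown class label {self.label!r}")
        for name in ("mean_nrcbv_sd", "psr_sd", "intra_tumor_cbv_cv",
                     "intra_tumor_psr_sd", "dispersion_jitter", "leak_scale"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0 <= self.leak_prob <= 1:
            raise ParameterError("leak_prob must lie in [0, 1]")


def cohort_presets() -> tuple[ClassPreset, ClassPreset]:
    """Default (oligodendroglioma, astrocytoma) presets.

    Population means/SDs are the published per-tumor mean nrCBV and PSR of
    1p19q-codeleted oligodendrogliomas (2.05 ± 0.58, 0.68 ± 0.21) and
    IDH-mutant astrocytomas (1.55 ± 0.58, 0.81 ± 0.19); the intra-tumor
    dispersion defaults put the simulated nrCBV p75 near the published
    per-class p75 values (2.53 and 1.86).
    """
    oligo = ClassPreset(
        label="oligodendroglioma",
        mean_nrcbv_mu=2.05, mean_nrcbv_sd=0.58,
        psr_mu=0.68, psr_sd=0.21,
    )
    astro = ClassPreset(
        label="astrocytoma",
        mean_nrcbv_mu=1.55, mean_nrcbv_sd=0.58,
        psr_mu=0.81, psr_sd=0.19,
    )
    return oligo, astro


# ---------------------------------------------------------------------------
# Bolus template
# ---------------------------------------------------------------------------

def _gamma_variate(tau: np.ndarray, alpha: float, beta: float) -> np.ndarray:
    """Gamma-variate normalized to unit peak (at tau = alpha*beta)."""
    g = np.zeros_like(tau)
    pos = tau > 0
    tp = tau[pos]
    g[pos] = (tp / (alpha * beta)) ** alpha * np.exp(alpha - tp / beta)
    return g


@dataclass(frozen=True)
class BolusTemplate:
    """Concentration template shared by all voxels of one acquisition.

    ``conc`` is the bolus curve C(t) (1/s, unit-class blood volume) and
    ``cum`` its running integral; ``ref_conc`` is the noiseless NAWM
    reference relaxation curve R_ref = C + q_n·∫C and ``ref_cum`` its running
    integral — the plateau/leakage basis every voxel is built on.  All
    arrays live on the acquisition time grid.
    """

    acq: AcquisitionParams
    conc: np.ndarray
    cum: np.ndarray
    ref_conc: np.ndarray
    ref_cum: np.ndarray
    nawm_plateau_coef: float
    i_arrival: int
    i_peak: int
    i_fpe: int


def make_bolus_template(
    acq: AcquisitionParams,
    peak_delta_r2star: float = 10.0,
    alpha: float = 3.0,
    beta: float = 2.0,
    recirc_delay_dyn: int = 8,
    recirc_amplitude: float = 0.15,
    recirc_broadening: float = 3.0,
) -> BolusTemplate:
    """Build the bolus template for one acquisition.

    The first pass is a gamma-variate (alpha=3, scale ~2 s → ≈12 s bolus
    width) peaking at ``peak_delta_r2star``; recirculation is a second
    gamma delayed by ``recirc_delay_dyn``·TR, broadened 3x and scaled to 15%
    amplitude — low and wide enough that the bare reference curve recovers
    close to the NAWM PSR on its own.  The NAWM plateau coefficient q_n is
    then a small correction, calibrated so the reference curve recovers to
    exactly the NAWM PSR at its detected first-pass end.
    """
    t = acq.times
    t0 = acq.arrival_index * acq.tr
    tau = t - t0
    g1 = _gamma_variate(tau, alpha, beta)
    g2 = recirc_amplitude * _gamma_variate(
        tau - recirc_delay_dyn * acq.tr, alpha, beta * recirc_broadening
    )
    conc = peak_delta_r2star * (g1 + g2)
    cum = cumulative_trapezoid(conc, dx=acq.tr, initial=0.0)
    i_peak = int(np.argmax(conc))
    post = np.nonzero((g1 < 0.05) & (tau > alpha * beta))[0]
    i_fpe = int(post[0]) if post.size else acq.n_dynamics - 1

    q_n = _calibrate_plateau(NAWM_CBV_RATIO * conc, cum, NAWM_PSR, acq)
    ref_conc = conc + q_n * cum
    ref_cum = cumulative_trapezoid(ref_conc, dx=acq.tr, initial=0.0)
    return BolusTemplate(
        acq=acq, conc=conc, cum=cum, ref_conc=ref_conc, ref_cum=ref_cum,
        nawm_plateau_coef=q_n, i_arrival=acq.arrival_index, i_peak=i_peak,
        i_fpe=i_fpe,
    )


def _calibrate_plateau(
    r_base: np.ndarray, basis: np.ndarray, psr: float, acq: AcquisitionParams,
    t_min_window: int = 20,
) -> float:
    """Plateau coefficient q making the noiseless PSR equal ``psr``.

    Inverts the signal equation in closed form — the plateau signal level is
    S_plateau = S_min + psr·(s0 − S_min), hence the target relaxation rate
    is R_target = −ln(S_plateau/s0)/TE and q = (R_target − R_base(fpe)) /
    basis(fpe) — and iterates because the signal minimum and the detected
    first-pass end both move (slightly) with q.
    """
    s0, te = acq.s0, acq.te
    q = 0.0
    fpe_prev = -1
    for _ in range(25):
        r = r_base + q * basis
        s = s0 * np.exp(-te * r)
        lo = acq.arrival_index
        hi = min(lo + t_min_window + 1, s.size)
        i_min = lo + int(np.argmin(s[lo:hi]))
        s_min = s[i_min]
        if s0 - s_min < 1e-9 * s0:
            return 0.0
        fpe, _ = first_pass_end_index(s, i_min)
        s_plateau = s_min + psr * (s0 - s_min)
        r_target = -np.log(s_plateau / s0) / te
        w = basis[fpe]
        if abs(w) <= 1e-9 * max(1.0, np.max(np.abs(basis))):
            return 0.0
        q_new = (r_target - r_base[fpe]) / w
        if fpe == fpe_prev and abs(q_new - q) < 1e-12 * max(1.0, abs(q)):
            return q_new
        fpe_prev, q = fpe, q_new
    return q


def simulate_curve(
    truth: VoxelTruth,
    template: BolusTemplate,
    acq: AcquisitionParams,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, dict]:
    """Simulate one voxel's time-intensity curve.

    The voxel relaxation curve is cbv_ratio·R_ref + (q + leak_k2)·∫R_ref
    with q calibrated (on the leak-free curve) so the measured early PSR
    equals ``psr_true`` in the noiseless limit.  Returns the signal array of
    length ``n_dynamics`` and a dict of construction markers
    (arrival/minimum/first-pass-end indices on the noiseless leak-free curve
    and the calibrated plateau coefficient).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if truth.bolus_delay == 0.0:
        ref, ref_cum = template.ref_conc, template.ref_cum
    else:
        t = acq.times
        ref = np.interp(t - truth.bolus_delay, t, template.ref_conc, left=0.0)
        ref_cum = np.interp(t - truth.bolus_delay, t, template.ref_cum, left=0.0)
    r_base = truth.cbv_ratio * ref
    plateau = _calibrate_plateau(r_base, ref_cum, truth.psr_true, acq)
    r_free = r_base + plateau * ref_cum
    s_free = acq.s0 * np.exp(-acq.te * r_free)
    lo = acq.arrival_index
    hi = min(lo + 21, s_free.size)
    i_min = lo + int(np.argmin(s_free[lo:hi]))
    fpe, fallback = (
        first_pass_end_index(s_free, i_min) if s_free[i_min] < acq.s0 else (lo, True)
    )
    r = r_free + truth.leak_k2 * ref_cum
    s = acq.s0 * np.exp(-acq.te * r)
    if acq.noise_sd > 0:
        s = s + rng.normal(0.0, acq.noise_sd, size=s.size)
    markers = {
        "arrival": acq.arrival_index,
        "t_min": i_min,
        "fpe": fpe,
        "fpe_fallback": fallback,
        "plateau_coef": plateau,
    }
    return s, markers


# ---------------------------------------------------------------------------
# Tumors and cohorts
# ---------------------------------------------------------------------------

def _truncated_normal(
    mu: float, sd: float, bounds: tuple[float, float],
    size: int | None, rng: np.random.Generator,
):
    if sd == 0:
        val = min(max(mu, bounds[0]), bounds[1])
        return val if size is None else np.full(size, val)
    a, b = (bounds[0] - mu) / sd, (bounds[1] - mu) / sd
    out = truncnorm.rvs(a, b, loc=mu, scale=sd, size=size or 1, random_state=rng)
    return float(out[0]) if size is None else out


def draw_tumor_truth(
    preset: ClassPreset, n_voxels: int, rng: np.random.Generator
) -> tuple[float, float, float, pd.DataFrame]:
    """Draw one tumor's population means and per-voxel truth table.

    Per-tumor mean CBV ratio and PSR come from the preset's (truncated
    normal) population distributions; voxel CBV ratios are lognormal around
    the tumor mean with the preset's CV (parameterized so the arithmetic
    mean equals the tumor mean), voxel PSRs truncated normal.
    """
    m_cbv = _truncated_normal(preset.mean_nrcbv_mu, preset.mean_nrcbv_sd, CBV_TRUNC, None, rng)
    m_psr = _truncated_normal(preset.psr_mu, preset.psr_sd, PSR_TRUNC, None, rng)
    leaky = rng.random() < preset.leak_prob
    k2 = float(rng.normal(0.0, preset.leak_scale)) if (leaky and preset.leak_scale > 0) else 0.0
    jit = preset.dispersion_jitter
    # per-tumor heterogeneity multiplier (mean 1) applied to both spreads
    disp = float(np.exp(rng.normal(-jit**2 / 2.0, jit))) if jit > 0 else 1.0
    cv = preset.intra_tumor_cbv_cv * disp
    if cv > 0:
        sigma = np.sqrt(np.log1p(cv**2))
        cbv = rng.lognormal(np.log(m_cbv) - sigma**2 / 2.0, sigma, size=n_voxels)
        cbv = np.clip(cbv, *CBV_TRUNC)  # same truncation as the population draws
    else:
        cbv = np.full(n_voxels, m_cbv)
    psr = _truncated_normal(
        m_psr, preset.intra_tumor_psr_sd * disp,
        (VOXEL_PSR_MIN, PSR_TRUNC[1]), n_voxels, rng,
    )
    table = pd.DataFrame({
        "cbv_ratio": cbv,
        "psr_true": np.asarray(psr, dtype=float),
        "leak_k2": k2,
        "bolus_delay": 0.0,
    })
    return m_cbv, m_psr, k2, table


@dataclass
class SyntheticTumor:
    """Simulated curves and ground truth for one patient."""

    label: str
    curves: np.ndarray  # (n_voxels, n_dynamics) tumor voxel signals
    nawm_curves: np.ndarray  # (n_nawm, n_dynamics) reference signals
    truth: pd.DataFrame  # per tumor voxel: cbv_ratio, psr_true, leak_k2, bolus_delay
    mean_cbv_ratio: float
    mean_psr: float
    leak_k2: float
    acq: AcquisitionParams


def simulate_tumor(
    preset: ClassPreset,
    n_voxels: int,
    acq: AcquisitionParams | None = None,
    seed: np.random.Generator | int | None = None,
    n_nawm: int = 50,
    template: BolusTemplate | None = None,
) -> SyntheticTumor:
    """Simulate one tumor (plus NAWM reference voxels) as raw curves."""
    if n_voxels < 10:
        raise ParameterError("n_voxels must be >= 10")
    acq = acq or AcquisitionParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = template or make_bolus_template(acq)
    m_cbv, m_psr, k2, truth = draw_tumor_truth(preset, n_voxels, rng)

    curves = np.empty((n_voxels, acq.n_dynamics))
    for i in range(n_voxels):
        vt = VoxelTruth(
            cbv_ratio=float(truth.cbv_ratio.iloc[i]),
            psr_true=float(min(truth.psr_true.iloc[i], PSR_MAX)),
            leak_k2=k2,
        )
        curves[i], _ = simulate_curve(vt, template, acq, rng)
    nawm = np.empty((n_nawm, acq.n_dynamics))
    nawm_truth = VoxelTruth(cbv_ratio=NAWM_CBV_RATIO, psr_true=NAWM_PSR)
    for i in range(n_nawm):
        nawm[i], _ = simulate_curve(nawm_truth, template, acq, rng)
    return SyntheticTumor(
        label=preset.label, curves=curves, nawm_curves=nawm, truth=truth,
        mean_cbv_ratio=m_cbv, mean_psr=m_psr, leak_k2=k2, acq=acq,
    )


def _ellipsoid_voxels(shape: tuple[int, int, int], n_voxels: int) -> np.ndarray:
    """Indices of the ``n_voxels`` most central voxels of a centered ellipsoid.

    Tumor occupies the mid-slices; returned as an (n, 3) integer array in a
    deterministic (radius, raster) order.
    """
    nx, ny, nz = shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    ax, ay, az = nx / 2.2, ny / 2.2, max(nz / 2.8, 1.0)
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r2 = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2
    flat = np.argsort(r2, axis=None, kind="stable")[:n_voxels]
    if r2.flat[flat[-1]] > 1.0:
        raise ParameterError(
            f"volume {shape} too small for a {n_voxels}-voxel ellipsoid tumor"
        )
    return np.column_stack(np.unravel_index(flat, shape))


def _nawm_boxes(shape: tuple[int, int, int], n_nawm: int) -> np.ndarray:
    """Two boxes of reference voxels on the first two slices (away from tumor)."""
    per_box = (n_nawm + 1) // 2
    side = int(np.ceil(np.sqrt(per_box)))
    coords = []
    for z, count in ((0, per_box), (1, n_nawm - per_box)):
        made = 0
        for dx in range(side + 2):
            for dy in range(side + 2):
                if made >= count:
                    break
                coords.append((dx, dy, z))
                made += 1
    return np.asarray(coords[:n_nawm], dtype=int)


def assemble_patient(
    tumor: SyntheticTumor,
    shape: tuple[int, int, int] = (24, 24, 10),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Embed simulated curves into a 4D volume with tumor and NAWM masks.

    The tumor is an ellipsoid in the central slices; the NAWM voxels form two
    boxes on the two lowest slices (mimicking reference ROIs on contiguous
    slices).  Background voxels hold baseline signal plus noise.  Returns
    ``(data_4d, tumor_mask, nawm_mask)``.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    acq = tumor.acq
    n_t = acq.n_dynamics
    data = np.full(shape + (n_t,), acq.s0, dtype=float)
    if acq.noise_sd > 0:
        data += rng.normal(0.0, acq.noise_sd, size=data.shape)
    tumor_mask = np.zeros(shape, dtype=np.uint8)
    nawm_mask = np.zeros(shape, dtype=np.uint8)
    tv = _ellipsoid_voxels(shape, tumor.curves.shape[0])
    nv = _nawm_boxes(shape, tumor.nawm_curves.shape[0])
    # masks must be disjoint: the ellipsoid lives in mid-slices, boxes in z=0,1
    for (x, y, z), curve in zip(tv, tumor.curves):
        data[x, y, z] = curve
        tumor_mask[x, y, z] = 1
    for (x, y, z), curve in zip(nv, tumor.nawm_curves):
        if tumor_mask[x, y, z]:
            raise ParameterError("tumor and NAWM masks overlap; enlarge the volume")
        data[x, y, z] = curve
        nawm_mask[x, y, z] = 1
    return data, tumor_mask, nawm_mask


def simulate_cohort(
    out_dir: str | Path,
    n_oligo: int = 24,
    n_astro: int = 28,
    n_voxels: int = 300,
    shape: tuple[int, int, int] = (24, 24, 10),
    acq: AcquisitionParams | None = None,
    presets: tuple[ClassPreset, ClassPreset] | None = None,
    seed: int = 0,
    n_nawm: int = 50,
) -> pd.DataFrame:
    """Simulate a two-class cohort and persist it as NIfTI volumes + CSV truth.

    Writes, per patient, ``dsc.nii.gz``, ``tumor_mask.nii.gz``,
    ``nawm_mask.nii.gz`` and ``voxel_truth.csv`` under
    ``out_dir/patient_###/``, plus a cohort-level ``truth.csv`` and a
    ``cohort.json`` config echo.  Deterministic for a given seed.
    """
    import nibabel as nib

    if n_oligo < 1 or n_astro < 1:
        raise ParameterError("need at least one patient per class")
    acq = acq or AcquisitionParams()
    shape = tuple(shape)
    oligo, astro = presets or cohort_presets()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = make_bolus_template(acq)
    labels = [oligo] * n_oligo + [astro] * n_astro
    streams = np.random.SeedSequence(seed).spawn(len(labels))
    affine = np.diag([1.75, 1.75, 5.0, 1.0])
    rows = []
    for pid, (preset, ss) in enumerate(zip(labels, streams)):
        rng = np.random.default_rng(ss)
        tumor = simulate_tumor(preset, n_voxels, acq, rng, n_nawm=n_nawm, template=template)
        data, tmask, nmask = assemble_patient(tumor, shape, rng)
        pdir = out_dir / f"patient_{pid:03d}"
        pdir.mkdir(exist_ok=True)
        hdr = nib.Nifti1Image(data.astype(np.float32), affine)
        hdr.header["pixdim"][4] = acq.tr
        nib.save(hdr, pdir / "dsc.nii.gz")
        nib.save(nib.Nifti1Image(tmask, affine), pdir / "tumor_mask.nii.gz")
        nib.save(nib.Nifti1Image(nmask, affine), pdir / "nawm_mask.nii.gz")
        tumor.truth.to_csv(pdir / "voxel_truth.csv", index=False)
        rows.append({
            "patient_id": f"patient_{pid:03d}",
            "label": preset.label,
            "mean_cbv_ratio": tumor.mean_cbv_ratio,
            "mean_psr": tumor.mean_psr,
            "leak_k2": tumor.leak_k2,
        })
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    config = {
        "seed": seed, "n_oligo": n_oligo, "n_astro": n_astro,
        "n_voxels": n_voxels, "n_nawm": n_nawm, "shape": list(shape),
        "acquisition": asdict(acq),
        "presets": [asdict(oligo), asdict(astro)],
    }
    (out_dir / "cohort.json").write_text(json.dumps(config, indent=2))
    return truth


def simulate_feature_cohort(
    n_oligo: int = 24,
    n_astro: int = 28,
    n_voxels: int = 300,
    presets: tuple[ClassPreset, ClassPreset] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a cohort feature table directly from voxel ground truth.

    Bypasses curve synthesis: per tumor, voxel truths are drawn from the
    preset population model and the 44 histogram features are computed on
    the truths themselves.  Statistically this matches what the signal
    pipeline recovers (the noiseless round trip is exact); it is the fast
    path for classifier-level experiments.
    """
    from .features import feature_vector_from_values

    oligo, astro = presets or cohort_presets()
    rng = np.random.default_rng(seed)
    rows = []
    for pid, preset in enumerate([oligo] * n_oligo + [astro] * n_astro):
        _, _, _, truth = draw_tumor_truth(preset, n_voxels, rng)
        feats = feature_vector_from_values(
            truth.cbv_ratio.to_numpy(), truth.psr_true.to_numpy()
        )
        rows.append({"patient_id": f"patient_{pid:03d}", "label": preset.label, **feats})
    return pd.DataFrame(rows)
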