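import numpy as np
import pytest

from perfquant import (
    AcquisitionParams,
    TimeCurve,
    VoxelTruth,
    cohort_presets,
    detect_bolus_markers,
    make_bolus_template,
    signal_to_delta_r2star,
    simulate_curve,
)
from perfquant.dsc import uncorrected_cbv


@pytest.fixture(scope="session")
def acq_noiseless():
    return AcquisitionParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def acq_snr50():
    return AcquisitionParams()


@pytest.fixture(scope="session")
def template_noiseless(acq_noiseless):
    return make_bolus_template(acq_noiseless)


@pytest.fixture(scope="session")
def template_snr50(acq_snr50):
    return make_bolus_template(acq_snr50)


@pytest.fixture(scope="session")
def presets():
    return cohort_presets()


@pytest.fixture(scope="session")
def noiseless_reference(acq_noiseless, template_noiseless):
    """Measured NAWM reference (curve, markers, ΔR2*, scalar rCBV), noiseless."""
    from perfquant.synthetic import NAWM_CBV_RATIO, NAWM_PSR

    signal, _ = simulate_curve(
        VoxelTruth(NAWM_CBV_RATIO, NAWM_PSR), template_noiseless, acq_noiseless, 0
    )
    curve = TimeCurve(signal, acq_noiseless.tr, acq_noiseless.te)
    markers = detect_bolus_markers(curve)
    conc = signal_to_delta_r2star(curve, markers)
    return curve, markers, conc, uncorrected_cbv(conc, markers)


def analyze_voxel(signal, acq, ref_conc, ref_rcbv):
    """Run the full single-voxel chain; returns (nrcbv, psr, markers, fit)."""
    from perfquant import compute_psr, corrected_cbv, fit_bsw

    curve = TimeCurve(signal, acq.tr, acq.te)
    markers = detect_bolus_markers(curve)
    conc = signal_to_delta_r2star(curve, markers)
    fit = fit_bsw(conc, ref_conc, markers)
    rcbv = corrected_cbv(conc, fit, ref_conc, markers)
    return rcbv / ref_rcbv, compute_psr(curve, markers), markers, fit


@pytest.fixture(scope="session")
def voxel_analyzer(acq_noiseless, noiseless_reference):
    _, _, ref_conc, ref_rcbv = noiseless_reference

    def run(signal):
        return analyze_voxel(signal, acq_noiseless, ref_conc, ref_rcbv)

    return run
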