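import numpy as np
import pytest

from qperf import (
    ArterialInput,
    ConcentrationCurve,
    Defect,
    GammaVariate,
    PhantomSpec,
    make_patient,
    quantify_map,
)

SLICE_ORDER = ("basal", "mid", "apical")

#: compact phantom used by most tests: small annuli keep per-slice fits fast
SMALL_RADII = {"basal": (8.0, 13.0), "mid": (7.0, 12.0), "apical": (6.0, 10.0)}


def small_spec(**overrides) -> PhantomSpec:
    kwargs = dict(
        image_size=64,
        radii=dict(SMALL_RADII),
        defects=(Defect(theta_start=60.0, theta_extent=90.0, mbf=1.11),),
        noise_sd=0.0,
        seed=11,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def gamma_aif() -> ArterialInput:
    times = np.arange(50, dtype=float)
    return ArterialInput(ConcentrationCurve(values=GammaVariate()(times), times=times))


@pytest.fixture(scope="session")
def noiseless_patient():
    """Ground truth, AIF and series for a noiseless wedge-defect phantom."""
    spec = small_spec()
    truth, aif, series = make_patient(spec)
    return spec, truth, aif, series


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_patient):
    """Quantified MBF maps for all three slices of the small phantom."""
    spec, truth, aif, series = noiseless_patient
    return {
        label: quantify_map(series[label], aif, truth[label].geometry)
        for label in SLICE_ORDER
    }
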