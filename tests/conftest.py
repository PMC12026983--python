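import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def flat_spectrum():
    """A featureless spectrum covering both GP channels."""
    from laurdan_gp import EmissionSpectrum

    wl = np.arange(400.0, 541.0)
    return EmissionSpectrum(
        wavelengths_nm=wl,
        intensities=np.full(wl.size, 100.0),
        temperature_C=25.0,
        sample_id="flat",
        lipid="none",
        assembly="other",
        replicate=1,
        scan=1,
    )


def make_gp_curve(temps, gp, sample_id="s", lipid="X", assembly="LUV"):
    from laurdan_gp import GPCurve

    temps = np.asarray(temps, float)
    gp = np.asarray(gp, float)
    return GPCurve(
        sample_id=sample_id,
        lipid=lipid,
        assembly=assembly,
        temperatures_C=temps,
        gp_mean=gp,
        gp_sd=np.full(temps.size, np.nan),
        n_replicates=np.ones(temps.size, dtype=int),
    )


@pytest.fixture
def gp_curve_factory():
    return make_gp_curve
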