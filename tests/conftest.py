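import numpy as np
import pytest

from popcsf import (
    SURFACE_PRO_4,
    CSFParams,
    LikelihoodTable,
    ParameterDomain,
    PsychometricSpec,
    StimulusDomain,
    cpp_to_cpd,
)


@pytest.fixture(scope="session")
def psy():
    return PsychometricSpec()


@pytest.fixture(scope="session")
def live_params():
    return ParameterDomain.live()


@pytest.fixture(scope="session")
def live_stim_cpd():
    """The live stimulus grid with frequencies converted to cpd at the
    nominal 500 mm viewing distance."""
    stim = StimulusDomain.live()
    return stim.with_frequencies_cpd(
        cpp_to_cpd(stim.frequencies, SURFACE_PRO_4, 500.0)
    )


@pytest.fixture(scope="session")
def live_lik(live_stim_cpd, live_params, psy):
    return LikelihoodTable.from_domains(live_stim_cpd, live_params, psy)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_small_domain(rng):
    """A random parameter domain of size <= 3x3x3x2 for fuzz tests."""
    ng = int(rng.integers(1, 4))
    nf = int(rng.integers(1, 4))
    nb = int(rng.integers(1, 4))
    nl = int(rng.integers(1, 3))
    g_lo = rng.uniform(2, 20)
    f_lo = rng.uniform(0.5, 3)
    lapses = sorted(set(np.round(rng.uniform(0.0, 0.3, size=nl), 3)))
    return ParameterDomain(
        gmax_grid=np.logspace(np.log10(g_lo), np.log10(g_lo * rng.uniform(2, 30)), ng),
        fmax_grid=np.logspace(np.log10(f_lo), np.log10(f_lo * rng.uniform(2, 8)), nf),
        beta_grid=np.linspace(rng.uniform(1, 3), rng.uniform(4, 9), nb),
        lapse_grid=np.array(lapses),
    )
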