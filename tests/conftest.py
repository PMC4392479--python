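import pytest

from pclicks.params import AccumulatorParams
from pclicks.reference import META_RAT
from pclicks.simulate import generate_dataset, simulate_choices


@pytest.fixture(scope="session")
def meta_params() -> AccumulatorParams:
    """Pooled-control best-fit parameters (the 'meta-rat')."""
    return META_RAT


@pytest.fixture(scope="session")
def ideal_params() -> AccumulatorParams:
    """Noise-free perfect integrator: a = #right - #left clicks."""
    return AccumulatorParams(lam=0.0, sigma_a2=0.0, sigma_s2=0.0, sigma_i2=0.0,
                             B=1000.0, phi=1.0, tau_phi=0.1, sho=0.0, lapse=0.0)


@pytest.fixture(scope="session")
def small_trialset(meta_params):
    """120 accumulation trials with meta-rat-simulated choices."""
    ts = generate_dataset(120, mixture={"accumulation": 1.0}, seed=101)
    return simulate_choices(ts, meta_params, seed=102)
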