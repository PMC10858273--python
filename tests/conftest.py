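import warnings

import pytest

from triadic_ug.agents import ResponderConfig, simulate_study
from triadic_ug.bayes import ConvergenceWarning, SamplerConfig
from triadic_ug.design import generate_design

# reduced but well-mixing sampler settings for test-time fits
FAST_SAMPLER = dict(draws=400, chains=4, warmup=800, check_diagnostics=False)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        yield


@pytest.fixture(scope="session")
def schedule():
    return generate_design("dyadic", "P1")


@pytest.fixture(scope="session")
def study_dataset():
    """Seven simulated triads under the default strategy pairing
    (reluctant-increase vs threshold outbidder, noisy maximizer responder)."""
    return simulate_study(n_triads=7, seed=42)


@pytest.fixture(scope="session")
def exact_responder_dataset():
    """Study with an error-free responder (weber_w = 0)."""
    return simulate_study(
        n_triads=3, seed=7, responder=ResponderConfig(weber_w=0.0, side_bias=0.5)
    )


def fast_config(seed: int) -> SamplerConfig:
    return SamplerConfig(seed=seed, **FAST_SAMPLER)
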