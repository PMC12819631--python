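import pytest
from hypothesis import HealthCheck, settings

from selhaz import SyntheticConfig, generate_population

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def det_world():
    """Small deterministic-policy world (no rate jitter, no reform)."""
    cfg = SyntheticConfig(n_per_wave=1500, seed=42, reform_effect=0.0, a_jitter_sd=0.0)
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def jittered_world():
    """Demo-scale world with reimbursement-rate jitter for the KDE stage."""
    cfg = SyntheticConfig(n_per_wave=2500, seed=7, a_jitter_sd=0.05)
    return cfg, generate_population(cfg)


@pytest.fixture(scope="session")
def big_det_world():
    """n = 5,000/wave deterministic world shared by the heavier checks."""
    cfg = SyntheticConfig(n_per_wave=5000, seed=5, reform_effect=0.0, a_jitter_sd=0.0)
    return cfg, generate_population(cfg)
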