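import numpy as np
import pytest

from hypoalgesia.synthetic_cohort import GenerativeConfig, default_psi


def make_config(**kw) -> GenerativeConfig:
    """Small, fast cohort configuration for unit tests."""
    base = dict(n_participants=12, n_trials=16, seed=123)
    base.update(kw)
    return GenerativeConfig(**base)


def noise_free_config(**kw) -> GenerativeConfig:
    """Deterministic generator: no residual noise, no random effects, no
    clipping or classification noise."""
    base = dict(
        n_participants=6,
        n_trials=16,
        psi=np.zeros((5, 5)),
        sigma_M=0.0,
        sigma_Y=0.0,
        clip=False,
        p_painful_high=1.0,
        p_painful_low=0.0,
        fast_guess_rate=0.0,
        seed=7,
    )
    base.update(kw)
    return GenerativeConfig(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def small_pain_table():
    """Cleaned high-temperature trials from a small simulated cohort."""
    from hypoalgesia.preprocess import filter_and_derive, select_analysis_set
    from hypoalgesia.synthetic_cohort import generate_participants, generate_trials

    cfg = make_config(clip=False, p_painful_high=1.0, fast_guess_rate=0.0)
    trials = generate_trials(generate_participants(cfg), cfg)
    clean, _ = filter_and_derive(trials)
    return select_analysis_set(clean, "PAIN")


__all__ = ["make_config", "noise_free_config"]
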