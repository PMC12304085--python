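"""Shared fixtures: small seeded simulations and simple vital-rate schedules."""

import numpy as np
import pytest

from nebench.demography import VitalRates, default_vital_rates
from nebench.forward_sim import SimConfig, run


@pytest.fixture(scope="session")
def rates():
    return default_vital_rates()


@pytest.fixture(scope="session")
def semelparous_rates():
    """Discrete generations: reproduce at age 1, then die."""
    return VitalRates(
        max_age=1,
        survival=np.array([1.0]),
        fertility=np.array([0.0, 1.0]),
        maturity_age=1,
    )


@pytest.fixture(scope="session")
def small_sim(rates):
    """Two-deme run at reduced cohort size (fast, reused read-only)."""
    cfg = SimConfig(
        rates=rates,
        cohort_size=200,
        migration=0.05,
        n_steps=40,
        sampling_start=35,
        sampling_end=40,
        seed=3,
    )
    return run(cfg)


@pytest.fixture(scope="session")
def founder_pop(semelparous_rates):
    """A founders-only population (no forward steps): every individual is a
    step-0 founder, so sampled genomes are pure coalescent draws."""
    cfg = SimConfig(
        rates=semelparous_rates,
        cohort_size=100,
        n_demes=1,
        migration=0.0,
        n_steps=0,
        sampling_start=1,
        sampling_end=0,
        seed=0,
    )
    return run(cfg)
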