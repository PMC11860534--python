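import dataclasses

import pytest

import hrsc
from hrsc import synthcardio as sc


@pytest.fixture(scope="session")
def population():
    """Small seeded population shared across tests."""
    return hrsc.generate_population(12, seed=42)


@pytest.fixture(scope="session")
def subject(population):
    return population[0]


@pytest.fixture(scope="session")
def male_35(population):
    """A 35-year-old male, for hand-checkable equation arithmetic."""
    base = next(p for p in population if p.sex == "male")
    return dataclasses.replace(base, age=35.0)


@pytest.fixture(scope="session")
def zero_noise():
    return sc.NoiseConfig.zero()


@pytest.fixture()
def heavy_target(subject):
    return hrsc.target_vo2(
        "heavy", 0.33, subject.vo2_rest, subject.vo2_get,
        subject.vo2_rcp, subject.vo2max_abs,
    )


@pytest.fixture()
def noiseless_trial(subject, heavy_target, zero_noise):
    """One noiseless 9-min heavy-domain trial with its ground truth."""
    return hrsc.simulate_constant_trial(
        subject, heavy_target, duration=540, seed=7, noise=zero_noise
    )
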