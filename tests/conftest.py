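import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from kmmdr import GenotypeMatrix, SurvivalSample, build_dataset, generate_penetrance
from kmmdr.simulate import SimulationConfig


@pytest.fixture(scope="session")
def strong_pair_dataset():
    """Cox-model dataset with a strong purely epistatic pair (SNP1, SNP2)."""
    pen = generate_penetrance(0.4, 0.4, seed=0)
    cfg = SimulationConfig(
        survival_model="cox", n=400, p=4, causal_pair=(0, 1),
        maf=0.4, h2=0.4, penetrance=pen, seed=11,
    )
    genotypes, sample, truth = build_dataset(cfg)
    return genotypes, sample, truth


@pytest.fixture
def toy_sample():
    """Ten subjects, mixed events and censoring, with ties."""
    time = np.array([2.0, 1.0, 3.0, 2.0, 5.0, 4.0, 1.0, 6.0, 3.0, 7.0])
    status = np.array([1, 1, 0, 1, 1, 0, 0, 1, 1, 0])
    return SurvivalSample(time, status)


def random_survival(rng, n, censor_prob=0.3, round_digits=None):
    """Small random right-censored sample (helper for oracle sweeps)."""
    t = rng.exponential(2.0, n)
    if round_digits is not None:
        t = np.round(t, round_digits) + 0.01  # keep times positive
    s = (rng.random(n) > censor_prob).astype(int)
    return t, s
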