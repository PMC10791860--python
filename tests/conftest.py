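import numpy as np
import pytest

from epimod.simulate import (SiteSpec, TraitSpec, simulate_cohort,
                             simulate_methylation)


@pytest.fixture(scope="session")
def linear_trait():
    """A single exactly-linear trait: p = age."""
    return TraitSpec("linear", gamma_mean=1.0, gamma_sd=0.0, q_mean=1.0, q_sd=0.0)


@pytest.fixture(scope="session")
def sqrt_trait():
    return TraitSpec("sqrt", gamma_mean=0.5, gamma_sd=0.0, q_mean=1.0, q_sd=0.0)


def make_linear_dataset(n_samples=60, n_sites=8, noise_sd=0.0, seed=0,
                        age_range=(1.0, 100.0)):
    """Noise-controlled dataset where methylation is affine in age."""
    trait = TraitSpec("linear", gamma_mean=1.0)
    cohort = simulate_cohort(n_samples, age_range, 0.0, [trait], seed=seed)
    rng = np.random.default_rng(seed + 1)
    sites = []
    for i in range(n_sites):
        sign = 1.0 if i % 2 == 0 else -1.0
        m0 = 0.2 if sign > 0 else 0.8
        rate = sign * rng.uniform(0.001, 0.004)
        sites.append(SiteSpec(f"s{i}", m0=m0, rate=rate, noise_sd=noise_sd,
                              trait_weights={"linear": 1.0}))
    matrix = simulate_methylation(cohort, sites, seed=seed + 2)
    return cohort, sites, matrix


@pytest.fixture()
def linear_dataset():
    return make_linear_dataset()
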