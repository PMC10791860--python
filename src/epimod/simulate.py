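"""Simulation of trait-associated DNA-methylation matrices.

The generative model treats a sample's latent "epigenetic state" as a weighted
sum of aging-associated phenotypes.  Each phenotype ``p_{k,j}`` for trait ``k``
and sample ``j`` follows

    p_{k,j} = age_j ** gamma_k * q_{k,j}

where ``gamma_k`` is a trait-level exponent (one draw per trait, shared across
samples) and ``q_{k,j}`` is a per-sample multiplicative exposure.  Exposures of
continuous traits are normal, optionally health-coupled: a latent health value
``h_j ~ N(0, health_sd^2)`` shifts the exposure mean of coupled traits.  Binary
traits take exposure ``binary_q`` with probability ``binary_prob`` and 1
otherwise, so deviations of ``binary_q`` from 1 encode an accelerating or
decelerating group effect (e.g. sex).

Methylation beta values at site ``i`` are linear in the site's own weighted
phenotype combination with additive Gaussian noise, clamped to the observable
range::

    m_ij = clip(m0_i + rate_i * sum_k w_ik p_{k,j} + eps_ij, 0, m_max_i)

All randomness flows from a single top-level seed through
``numpy.random.SeedSequence`` spawning, so per-trait and per-site streams are
stable: adding sites does not perturb earlier draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TraitSpec",
    "SiteSpec",
    "Cohort",
    "MethylationMatrix",
    "SimulationDesign",
    "realize_phenotype",
    "simulate_cohort",
    "simulate_methylation",
    "table1_design",
    "simulate_celltype_fractions",
    "split_half",
]


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# Trait and site specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """One simulated phenotype.

    Parameters
    ----------
    name:
        Trait identifier; sites reference traits by name.
    gamma_mean, gamma_sd:
        Mean and standard deviation of the trait exponent ``gamma``.  A single
        gamma is drawn per trait and shared across samples.  ``gamma = 1``
        gives a linear age association, ``0 < gamma < 1`` a concave one and
        ``gamma = 0`` an age-independent trait.
    q_mean, q_sd:
        Mean and standard deviation of the per-sample exposure ``q`` for
        continuous traits (dimensionless, centred near 1).
    health_coupled:
        If set, the sample's health value ``h_j`` shifts the exposure mean:
        ``q ~ N(q_mean + h_j, q_sd^2)``.
    binary, binary_q, binary_prob:
        Binary traits draw ``q = binary_q`` with probability ``binary_prob``
        and ``q = 1`` otherwise; ``q_sd`` is ignored for binary traits.
    """

    name: str
    gamma_mean: float
    gamma_sd: float = 0.0
    q_mean: float = 1.0
    q_sd: float = 0.0
    health_coupled: bool = False
    binary: bool = False
    binary_q: float = 1.0
    binary_prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.binary_prob <= 1.0:
            raise ValueError(f"binary_prob must be in [0, 1], got {self.binary_prob}")
        if self.q_sd < 0:
            raise ValueError("q_sd must be non-negative")
        if self.gamma_sd < 0:
            raise ValueError("gamma_sd must be non-negative")

    def expected_exposure(self) -> float:
        """Mean exposure, used to scale site rates to a target beta range."""
        if self.binary:
            return self.binary_prob * self.binary_q + (1.0 - self.binary_prob)
        return self.q_mean


@dataclass(frozen=True)
class SiteSpec:
    """Generative parameters of one methylation site.

    ``trait_weights`` maps trait names to non-negative weights; the direction
    of methylation change is carried by the sign of ``rate``.  Most sites have
    a single unit weight; mixture sites weight their assigned traits equally.
    """

    site_id: str
    m0: float
    rate: float
    noise_sd: float
    m_max: float = 1.0
    trait_weights: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.m0 <= self.m_max <= 1.0:
            raise ValueError(
                f"site {self.site_id}: need 0 <= m0 <= m_max <= 1, "
                f"got m0={self.m0}, m_max={self.m_max}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(w < 0 for w in self.trait_weights.values()):
            raise ValueError("trait weights must be non-negative")


# ---------------------------------------------------------------------------
# Cohort and matrix containers
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Simulated samples: ages, health values, realized phenotypes.

    ``phenotypes`` and ``binary_status`` are samples x traits frames indexed
    by sample id; ``binary_status`` is 0/1 and only meaningful for binary
    traits (0 elsewhere).  ``gammas`` records the realized per-trait exponent.
    """

    sample_ids: list[str]
    ages: np.ndarray
    health: np.ndarray
    phenotypes: pd.DataFrame
    binary_status: pd.DataFrame
    traits: tuple[TraitSpec, ...]
    gammas: dict[str, float]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, idx: Sequence[int]) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            sample_ids=[self.sample_ids[i] for i in idx],
            ages=self.ages[idx],
            health=self.health[idx],
            phenotypes=self.phenotypes.iloc[idx],
            binary_status=self.binary_status.iloc[idx],
            traits=self.traits,
            gammas=dict(self.gammas),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-sample metadata (age, health, status and phenotypes)."""
        out = pd.DataFrame(
            {"sample_id": self.sample_ids, "age": self.ages, "health": self.health}
        ).set_index("sample_id")
        status = self.binary_status.loc[:, [t.name for t in self.traits if t.binary]]
        out = out.join(status.add_prefix("status_"))
        return out.join(self.phenotypes.add_prefix("phenotype_"))


@dataclass
class MethylationMatrix:
    """Sites x samples beta-value matrix with identifiers.

    Values are in [0, 1] with no missing entries; column order matches the
    cohort sample order.  ``n_clamped`` records how many entries hit the
    [0, m_max] bounds during simulation (0 for matrices read from disk).
    """

    values: np.ndarray
    site_ids: list[str]
    sample_ids: list[str]
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite values")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, idx: Sequence[int]) -> "MethylationMatrix":
        idx = np.asarray(idx)
        return MethylationMatrix(
            self.values[:, idx],
            list(self.site_ids),
            [self.sample_ids[i] for i in idx],
        )

    def subset_sites(self, site_ids: Sequence[str]) -> "MethylationMatrix":
        index = {s: i for i, s in enumerate(self.site_ids)}
        missing = [s for s in site_ids if s not in index]
        if missing:
            raise KeyError(f"unknown sites: {missing[:5]}")
        rows = [index[s] for s in site_ids]
        return MethylationMatrix(self.values[rows], list(site_ids), list(self.sample_ids))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# Phenotype and cohort simulation
# ---------------------------------------------------------------------------

def realize_phenotype(trait: TraitSpec, age: float, health: float = 0.0,
                      rng: np.random.Generator | None = None,
                      gamma: float | None = None) -> float:
    """Realize one phenotype value ``p = age**gamma * q`` for one sample.

    ``gamma`` may be supplied to reuse a trait-level draw; otherwise it is
    drawn from ``N(gamma_mean, gamma_sd^2)`` (exactly ``gamma_mean`` when
    ``gamma_sd == 0``).  Negative ages are rejected because fractional powers
    of negative numbers are undefined.
    """
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    if rng is None:
        rng = np.random.default_rng()
    if gamma is None:
        gamma = float(rng.normal(trait.gamma_mean, trait.gamma_sd))
    if trait.binary:
        on = rng.random() < trait.binary_prob
        q = trait.binary_q if on else 1.0
    else:
        loc = trait.q_mean + (health if trait.health_coupled else 0.0)
        q = float(rng.normal(loc, trait.q_sd))
    if gamma == 0.0:
        return float(q)
    return float(age ** gamma * q)


def simulate_cohort(n_samples: int, age_range: tuple[float, float],
                    health_sd: float, traits: Sequence[TraitSpec],
                    seed) -> Cohort:
    """Simulate a cohort: ages ~ U(age_range), health ~ N(0, health_sd^2).

    One gamma is drawn per trait (shared across samples) and one exposure per
    sample per trait.  Deterministic under a fixed seed; per-trait streams are
    spawned from the top-level seed so trait draws are order-stable.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    lo, hi = age_range
    if not lo < hi:
        raise ValueError(f"age_range must satisfy lo < hi, got {age_range}")
    if lo < 0:
        raise ValueError("ages must be non-negative")
    if not traits:
        raise ValueError("at least one trait is required")
    names = [t.name for t in traits]
    if len(set(names)) != len(names):
        raise ValueError("trait names must be unique")

    ss = _seed_sequence(seed)
    streams = ss.spawn(2 + len(traits))
    ages = np.random.default_rng(streams[0]).uniform(lo, hi, n_samples)
    health = np.random.default_rng(streams[1]).normal(0.0, health_sd, n_samples)

    sample_ids = [f"S{j:05d}" for j in range(n_samples)]
    phen = {}
    status = {}
    gammas = {}
    for trait, stream in zip(traits, streams[2:]):
        rng_t = np.random.default_rng(stream)
        gamma = float(rng_t.normal(trait.gamma_mean, trait.gamma_sd))
        gammas[trait.name] = gamma
        if trait.binary:
            on = rng_t.random(n_samples) < trait.binary_prob
            q = np.where(on, trait.binary_q, 1.0)
            status[trait.name] = on.astype(int)
        else:
            loc = trait.q_mean + (health if trait.health_coupled else 0.0)
            q = rng_t.normal(loc, trait.q_sd, n_samples)
            status[trait.name] = np.zeros(n_samples, dtype=int)
        if gamma == 0.0:
            phen[trait.name] = q.astype(float)
        else:
            phen[trait.name] = ages ** gamma * q
    return Cohort(
        sample_ids=sample_ids,
        ages=ages,
        health=health,
        phenotypes=pd.DataFrame(phen, index=sample_ids),
        binary_status=pd.DataFrame(status, index=sample_ids),
        traits=tuple(traits),
        gammas=gammas,
    )


def simulate_methylation(cohort: Cohort, sites: Sequence[SiteSpec], seed) -> MethylationMatrix:
    """Simulate beta values for every site and sample.

    ``m_ij = clip(m0 + rate * sum_k w_k p_kj + eps, 0, m_max)`` with
    ``eps ~ N(0, noise_sd^2)``.  Per-site noise streams are spawned from the
    top-level seed.  The number of clamped entries is logged and recorded.
    """
    known = set(cohort.phenotypes.columns)
    for site in sites:
        unknown = set(site.trait_weights) - known
        if unknown:
            raise KeyError(
                f"site {site.site_id} references unknown traits: {sorted(unknown)}"
            )
    ss = _seed_sequence(seed)
    streams = ss.spawn(len(sites))
    n = cohort.n_samples
    values = np.empty((len(sites), n))
    n_clamped = 0
    P = cohort.phenotypes
    for i, (site, stream) in enumerate(zip(sites, streams)):
        state = np.zeros(n)
        for name, w in site.trait_weights.items():
            state += w * P[name].to_numpy()
        mu = site.m0 + site.rate * state
        eps = np.random.default_rng(stream).normal(0.0, site.noise_sd, n)
        raw = mu + eps
        clipped = np.clip(raw, 0.0, site.m_max)
        n_clamped += int(np.count_nonzero(raw != clipped))
        values[i] = clipped
    frac = n_clamped / values.size if values.size else 0.0
    logger.info(
        "simulated %d x %d methylation matrix; clamped %d entries (%.2f%%)",
        len(sites), n, n_clamped, 100 * frac,
    )
    return MethylationMatrix(
        values=values,
        site_ids=[s.site_id for s in sites],
        sample_ids=list(cohort.sample_ids),
        n_clamped=n_clamped,
    )


# ---------------------------------------------------------------------------
# Study design: traits, sites and site-parameter draws
# ---------------------------------------------------------------------------

@dataclass
class SimulationDesign:
    """A complete simulation design: traits, sites and cohort parameters."""

    traits: tuple[TraitSpec, ...]
    sites: tuple[SiteSpec, ...]
    n_samples: int = 500
    age_range: tuple[float, float] = (0.0, 100.0)
    health_sd: float = 0.0


def _expected_span(trait: TraitSpec, age_range: tuple[float, float]) -> float:
    """Expected phenotype span over the cohort, used to scale site rates."""
    lo, hi = age_range
    g = trait.gamma_mean
    if g == 0.0:
        # age-independent trait: spread comes from the exposure itself
        return max(2.0 * trait.q_sd, 1e-6)
    return (hi ** g - lo ** g) * trait.expected_exposure()


def _draw_site(site_id: str, weights: Mapping[str, float],
               traits_by_name: Mapping[str, TraitSpec],
               age_range: tuple[float, float],
               rng: np.random.Generator) -> SiteSpec:
    """Draw site parameters.

    Hypermethylating sites (probability 1/2) start low (m0 ~ U(0.05, 0.35),
    positive rate); hypomethylating sites start high (m0 ~ U(0.65, 0.95),
    negative rate).  |rate| is scaled so that the expected beta range of the
    site over the cohort's phenotype span is U(0.1, 0.5), which keeps sites
    age-informative while staying inside [0, 1].  noise_sd ~ U(0.003, 0.01).
    """
    hyper = rng.random() < 0.5
    m0 = rng.uniform(0.05, 0.35) if hyper else rng.uniform(0.65, 0.95)
    target_range = rng.uniform(0.1, 0.5)
    span = sum(
        w * _expected_span(traits_by_name[name], age_range)
        for name, w in weights.items()
    )
    rate = (1.0 if hyper else -1.0) * target_range / max(span, 1e-12)
    noise_sd = rng.uniform(0.003, 0.01)
    return SiteSpec(
        site_id=site_id, m0=m0, rate=rate, noise_sd=noise_sd,
        m_max=1.0, trait_weights=dict(weights),
    )


def table1_design(binary_q: float = 0.995, health_sd: float = 0.0, seed=0,
                  n_samples: int = 500,
                  age_range: tuple[float, float] = (0.0, 100.0),
                  sites_per_continuous: int = 5,
                  binary_sites: int = 50,
                  mixture_sites: int = 50,
                  total_sites: int | None = None,
                  q_sd: float = 0.05,
                  gamma_sd: float = 0.01) -> SimulationDesign:
    """Build the benchmark study design: 61 traits and 400 sites.

    Traits: 10 health-coupled continuous traits with gamma ~ N(0.5, gamma_sd^2),
    10 health-coupled with gamma ~ N(1.0, gamma_sd^2), 20 age-only at each of
    the two gamma means, and one binary trait (gamma = 0.5 exactly,
    binary_prob = 0.5, exposure ``binary_q`` when "on").  Sample-effect
    (health-coupled) traits carry per-sample exposure noise ``q_sd``; age-only
    traits are deterministic functions of age (q = 1).  Sites: 5 per
    continuous trait, 50 for the binary trait and 50 mixture sites equally
    weighting four randomly chosen continuous traits plus the binary trait
    (weight 1/5 each), for 400 sites total.  ``total_sites=450`` pads with
    additional single-trait continuous sites.
    """
    if not 0.995 <= binary_q <= 1.0:
        raise ValueError(f"binary_q must be in [0.995, 1.0], got {binary_q}")
    traits: list[TraitSpec] = []
    for i in range(10):
        traits.append(TraitSpec(f"health_sqrt_{i:02d}", 0.5, gamma_sd,
                                q_sd=q_sd, health_coupled=True))
    for i in range(10):
        traits.append(TraitSpec(f"health_lin_{i:02d}", 1.0, gamma_sd,
                                q_sd=q_sd, health_coupled=True))
    for i in range(20):
        traits.append(TraitSpec(f"age_sqrt_{i:02d}", 0.5, gamma_sd))
    for i in range(20):
        traits.append(TraitSpec(f"age_lin_{i:02d}", 1.0, gamma_sd))
    binary = TraitSpec("binary", 0.5, 0.0, binary=True,
                       binary_q=binary_q, binary_prob=0.5)
    traits.append(binary)
    traits_by_name = {t.name: t for t in traits}
    continuous = [t for t in traits if not t.binary]

    rng = np.random.default_rng(_seed_sequence(seed))
    sites: list[SiteSpec] = []
    for trait in continuous:
        for k in range(sites_per_continuous):
            sites.append(_draw_site(
                f"site_{trait.name}_{k}", {trait.name: 1.0},
                traits_by_name, age_range, rng))
    for k in range(binary_sites):
        sites.append(_draw_site(
            f"site_binary_{k:02d}", {binary.name: 1.0},
            traits_by_name, age_range, rng))
    for k in range(mixture_sites):
        chosen = rng.choice(len(continuous), size=4, replace=False)
        weights = {continuous[c].name: 0.2 for c in chosen}
        weights[binary.name] = 0.2
        sites.append(_draw_site(
            f"site_mixture_{k:02d}", weights, traits_by_name, age_range, rng))
    if total_sites is not None:
        if total_sites < len(sites):
            raise ValueError(
                f"total_sites={total_sites} below enumerated count {len(sites)}")
        for k in range(total_sites - len(sites)):
            trait = continuous[int(rng.integers(len(continuous)))]
            sites.append(_draw_site(
                f"site_pad_{k:02d}", {trait.name: 1.0},
                traits_by_name, age_range, rng))
    return SimulationDesign(
        traits=tuple(traits), sites=tuple(sites),
        n_samples=n_samples, age_range=age_range, health_sd=health_sd,
    )


# ---------------------------------------------------------------------------
# Covariate fixtures and sample splitting
# ---------------------------------------------------------------------------

def simulate_celltype_fractions(cohort: Cohort, n_types: int = 6,
                                age_drift: float = 0.0, seed=0) -> pd.DataFrame:
    """Compositional cell-type fractions from an age-drifting Dirichlet.

    Base concentrations decrease across types (one dominant type, several
    minor ones, loosely blood-like).  ``age_drift`` (per year) tilts the
    concentrations linearly with age, alternating direction across types, so
    fractions become age-correlated; at ``age_drift=0`` they are age-null.
    Rows are non-negative and sum to 1.
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    base = np.linspace(8.0, 2.0, n_types)
    signs = np.where(np.arange(n_types) % 2 == 0, 1.0, -1.0)
    centered = cohort.ages - cohort.ages.mean()
    conc = base[None, :] * (1.0 + age_drift * centered[:, None] * signs[None, :])
    conc = np.clip(conc, 0.05, None)
    rng = np.random.default_rng(_seed_sequence(seed))
    g = rng.standard_gamma(conc)
    fractions = g / g.sum(axis=1, keepdims=True)
    cols = [f"celltype_{t}" for t in range(n_types)]
    return pd.DataFrame(fractions, index=cohort.sample_ids, columns=cols)


def split_half(matrix: MethylationMatrix, cohort: Cohort, seed):
    """Random half split into (train, test) pairs of (matrix, cohort).

    Disjoint, exhaustive, sizes differ by at most one; deterministic under
    the seed.
    """
    n = cohort.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    if matrix.sample_ids != cohort.sample_ids:
        raise ValueError("matrix and cohort sample order disagree")
    perm = np.random.default_rng(_seed_sequence(seed)).permutation(n)
    n_train = (n + 1) // 2
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    train = (matrix.subset_samples(train_idx), cohort.subset(train_idx))
    test = (matrix.subset_samples(test_idx), cohort.subset(test_idx))
    return train, test
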