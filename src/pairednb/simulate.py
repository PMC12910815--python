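"""Synthetic paired-count generators: the package's simulation testbed.

Four generative laws for the per-cell counts are supported, all sharing the
latent-factor regression structure mu[s,i] = exp(gamma_i + log N[s,i] +
x_i' beta_s):

* ``NB``          — NB(mu, alpha_s) with variance (1 + mu alpha) mu
                    (alpha = 0 falls back to Poisson);
* ``Lomax``       — heavy-tailed Lomax with shape 2 and mean mu (scale =
                    mu; infinite variance), rounded half-up to an integer;
* ``Exponential`` — exponential with mean mu, rounded half-up;
* ``Poisson``     — Poisson(mu).

Sequencing depths are drawn from a shifted negative binomial,
N ~ NB(m, a) + shift, reproducing the right-skewed depth distributions of
real amplicon runs.  Latent factors gamma_i are normal with the mean-one
constraint E exp(gamma) = 1 (mean -phi^2/2, variance phi^2), optionally
with two or more variance levels allocated at random across samples; a
zero-centered N(0, v) law is also available for benchmark scenarios that
specify it.  The named scenarios returned by :func:`make_scenario` are the
package's standard benchmark conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .datamodel import PairedCountData

__all__ = [
    "ScenarioConfig", "SCENARIOS", "make_scenario",
    "gen_covariates", "gen_depths", "gen_latent_factors", "gen_counts",
    "sparsity", "simulate_dataset", "simulate_replicates",
]

LAWS = ("NB", "Lomax", "Exponential", "Poisson")


@dataclass
class ScenarioConfig:
    """Fully parameterized synthetic scenario.

    ``phi2_levels``/``phi2_probs`` describe the latent-factor variance
    structure: a single level, or several levels with allocation
    probabilities.  ``gamma_centered`` selects the mean-one prior centering
    (mean -phi^2/2) versus a plain zero-centered normal.
    """

    name: str = "custom"
    law: str = "NB"
    n: int = 300
    beta: tuple = ((-10.0, 0.03, 0.03), (-9.0, 0.02, 0.01))
    alpha: tuple = (2.0, 1.0)
    phi2_levels: tuple = (0.0,)
    phi2_probs: tuple | None = None
    gamma_centered: bool = True
    exact_split: bool = False
    covariate_law: str = "table1"
    depth_params: tuple = ((8_000_000, 1.0, 8_000_000),
                          (2_000_000, 1.0, 2_000_000))
    replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.law not in LAWS:
            raise ValueError(f"unknown generative law {self.law!r}")
        if self.n < 1 or self.replicates < 1:
            raise ValueError("n and replicate count must be >= 1")
        if any(v < 0 for v in self.phi2_levels):
            raise ValueError("phi^2 levels must be non-negative")
        if self.phi2_probs is not None:
            p = np.asarray(self.phi2_probs, float)
            if p.size != len(self.phi2_levels) or np.any(p < 0) \
                    or not np.isclose(p.sum(), 1.0):
                raise ValueError("phi2_probs must be a probability vector "
                                 "matching phi2_levels")
        for m, a, shift in self.depth_params:
            if m <= 0 or a < 0 or shift < 0:
                raise ValueError("depth parameters must satisfy m>0, a>=0, shift>=0")


def gen_covariates(n: int, law: str, rng: np.random.Generator) -> np.ndarray:
    """n x 3 design: intercept plus two covariates per the named law.

    ``table1``: x2 ~ Unif(20, 80), x3 ~ Bern(0.3).
    ``table2``: x2 ~ N(5, 1), x3 ~ N(0, 1).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if law == "table1":
        x2 = rng.uniform(20.0, 80.0, n)
        x3 = rng.binomial(1, 0.3, n).astype(float)
    elif law == "table2":
        x2 = rng.normal(5.0, 1.0, n)
        x3 = rng.normal(0.0, 1.0, n)
    else:
        raise ValueError(f"unknown covariate law {law!r}")
    return np.column_stack([np.ones(n), x2, x3])


def gen_depths(n: int, m: float, a: float, shift: float,
               rng: np.random.Generator) -> np.ndarray:
    """Shifted-NB sequencing depths: NB(mean m, overdispersion a) + shift.

    Marginal mean m + shift; right-skewed for a > 0; a = 0 is the Poisson
    special case with variance ~ m.
    """
    if m <= 0 or a < 0 or shift < 0:
        raise ValueError("require m > 0, a >= 0, shift >= 0")
    if a == 0:
        draw = rng.poisson(m, n)
    else:
        r = 1.0 / a
        draw = rng.negative_binomial(r, r / (r + m), n)
    return (draw + int(shift)).astype(np.int64)


def gen_latent_factors(n: int, phi2_levels, phi2_probs, rng: np.random.Generator,
                       centered: bool = True, exact_split: bool = False
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Draw gamma_i plus the per-sample variance-level allocation (1-based).

    With ``centered=True`` each gamma_i ~ N(-phi2/2, phi2) so that
    E exp(gamma) = 1 and Var exp(gamma) = exp(phi2) - 1.  ``exact_split``
    allocates levels in exact proportions instead of i.i.d. sampling.
    """
    levels = np.asarray(phi2_levels, dtype=float)
    if np.any(levels < 0):
        raise ValueError("phi^2 must be non-negative")
    if phi2_probs is None:
        alloc = np.zeros(n, dtype=np.int64)
    else:
        probs = np.asarray(phi2_probs, dtype=float)
        if exact_split:
            sizes = np.floor(probs * n).astype(int)
            while sizes.sum() < n:
                sizes[int(np.argmax(probs * n - sizes))] += 1
            alloc = np.repeat(np.arange(levels.size), sizes)
            rng.shuffle(alloc)
        else:
            alloc = rng.choice(levels.size, size=n, p=probs)
    v = levels[alloc]
    mean = -v / 2.0 if centered else 0.0
    gamma = rng.normal(mean, np.sqrt(v))
    return gamma, alloc + 1


def gen_counts(X: np.ndarray, beta, gamma: np.ndarray, N: np.ndarray,
               law: str, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Draw one site's counts under the named law at mean
    mu = exp(gamma + log N + X' beta)."""
    logmu = gamma + np.log(N) + X @ np.asarray(beta, dtype=float)
    mu = np.exp(logmu)
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError("non-finite count mean")
    if law == "NB":
        if alpha == 0:
            return rng.poisson(mu).astype(np.int64)
        r = 1.0 / alpha
        return rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
    if law == "Lomax":
        draw = mu * rng.pareto(2.0, size=mu.shape)
    elif law == "Exponential":
        draw = rng.exponential(mu)
    elif law == "Poisson":
        return rng.poisson(mu).astype(np.int64)
    else:
        raise ValueError(f"unknown generative law {law!r}")
    return np.floor(draw + 0.5).astype(np.int64)  # round half-up


def sparsity(y) -> float:
    """Proportion of zero counts."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty count vector")
    return float(np.mean(y == 0))


def simulate_dataset(cfg: ScenarioConfig, seed=None
                     ) -> tuple[PairedCountData, dict]:
    """Generate one replicate; returns (data, truth).

    ``truth`` records beta, alpha, gamma, phi2 levels and the per-sample
    allocation (consumable as the group variable for JNBM_SG).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    X = gen_covariates(cfg.n, cfg.covariate_law, rng)
    depths = np.stack([gen_depths(cfg.n, *cfg.depth_params[s], rng)
                       for s in range(2)])
    gamma, alloc = gen_latent_factors(cfg.n, cfg.phi2_levels, cfg.phi2_probs,
                                      rng, centered=cfg.gamma_centered,
                                      exact_split=cfg.exact_split)
    counts = np.stack([
        gen_counts(X, cfg.beta[s], gamma, depths[s], cfg.law,
                   cfg.alpha[s] if cfg.law == "NB" else 0.0, rng)
        for s in range(2)])
    # synthetic depths are independent offsets, not column sums, so a
    # heavy-tailed count may exceed them; keep the offset interpretation
    depths = np.maximum(depths, counts)
    groups = None
    if cfg.phi2_probs is not None:
        # relabel to a contiguous 1..L_obs set in case a level drew no sample
        groups = np.searchsorted(np.unique(alloc), alloc) + 1
    data = PairedCountData(counts=counts, depths=depths, covariates=X,
                           group_labels=groups,
                           taxon=cfg.name)
    truth = {"beta": np.asarray(cfg.beta, dtype=float),
             "alpha": np.asarray(cfg.alpha, dtype=float),
             "gamma": gamma, "allocation": alloc,
             "phi2_levels": np.asarray(cfg.phi2_levels, dtype=float)}
    return data, truth


def simulate_replicates(cfg: ScenarioConfig, seed: int | None = None
                        ) -> Iterator[tuple[PairedCountData, dict]]:
    """Yield ``cfg.replicates`` independent datasets, reproducibly keyed by
    (scenario, seed)."""
    master = np.random.SeedSequence(cfg.seed if seed is None else seed)
    for child in master.spawn(cfg.replicates):
        yield simulate_dataset(cfg, seed=child)


_TABLE2_BASE = dict(
    law="Lomax", n=100,
    beta=((0.0, -3.0, 1.0), (-3.0, -2.0, 1.5)),
    alpha=(0.0, 0.0),
    phi2_levels=(5.0,), phi2_probs=None, gamma_centered=False,
    covariate_law="table2",
    depth_params=((200_000, 1.0, 200_000), (100_000, 1.0, 100_000)),
)

SCENARIOS: dict[str, dict] = {
    "table1_phi0": dict(phi2_levels=(0.0,)),
    "table1_phi1": dict(phi2_levels=(1.0,)),
    "table1_phi5": dict(phi2_levels=(5.0,)),
    "table1_mix": dict(phi2_levels=(0.5, 10.0), phi2_probs=(0.2, 0.8)),
    "table2_lomax": dict(_TABLE2_BASE),
    "table3_smaller_n": dict(_TABLE2_BASE, n=50),
    "table3_larger_depth": dict(_TABLE2_BASE, depth_params=(
        (800_000, 1.0, 800_000), (300_000, 1.0, 300_000))),
    "table3_smaller_depth": dict(_TABLE2_BASE, depth_params=(
        (70_000, 1.0, 70_000), (40_000, 1.0, 40_000))),
    "table3_exponential": dict(_TABLE2_BASE, law="Exponential"),
    "table3_poisson": dict(_TABLE2_BASE, law="Poisson"),
}


def make_scenario(name: str, **overrides) -> ScenarioConfig:
    """Return the named benchmark scenario, optionally with overrides."""
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; choose from "
                       f"{sorted(SCENARIOS)}")
    kw = dict(SCENARIOS[name])
    kw.update(overrides)
    return ScenarioConfig(name=name, **kw)
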