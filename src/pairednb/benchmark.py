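"""Simulation benchmark driver: scenario -> fits -> coefficient-MSE table.

Runs a named synthetic scenario for R replicates, fits the requested
models to every replicate, and tabulates the MSE of the posterior-mean
(or GMM point-estimate) regression coefficients against the generating
truth, in the layout of the package's benchmark tables.  Model names:
``SNBM``, ``JNBM``, ``JNBM_SG``, ``JNBM_Mix``, and ``GMM:<pc>`` where
``<pc>`` is a pseudocount (e.g. ``GMM:1e-7``) or ``GMM:data-dependent``.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import McmcConfig, ModelSpec
from .gmm import fit_gmm_counts
from .metrics import coefficient_mse
from .models import fit
from .simulate import make_scenario, simulate_dataset

__all__ = ["BenchmarkReport", "run_benchmark"]


@dataclass
class BenchmarkReport:
    scenario: str
    models: list[str]
    replicates: int
    mse: pd.DataFrame
    seeds: list[int] = field(default_factory=list)
    runtime_s: float = 0.0
    failures: int = 0

    def table(self) -> pd.DataFrame:
        """Wide table: one row per model, columns (site, covariate)."""
        wide = self.mse.pivot(index="model", columns=["site", "covariate"],
                              values="mse")
        return wide.reindex(self.models)


def _fit_one(model: str, data, truth, mcmc: McmcConfig, chain_seed: int,
             rng: np.random.Generator) -> np.ndarray:
    """Posterior-mean (or point-estimate) coefficients for one replicate."""
    if model.startswith("GMM:"):
        rule = model.split(":", 1)[1]
        try:
            rule = float(rule)
        except ValueError:
            pass
        return fit_gmm_counts(data, rule).beta
    kw = {}
    if model == "JNBM_SG" and data.group_labels is None:
        # no heterogeneity in truth: assign two groups at random
        data = data.replace(group_labels=1 + (np.arange(data.n)
                                              % 2)[rng.permutation(data.n)])
    if model == "JNBM_Mix":
        kw["L"] = 3
    spec = ModelSpec(model=model,
                     mcmc=dataclasses.replace(mcmc, seed=chain_seed), **kw)
    return fit(data, spec).beta_mean()


def run_benchmark(scenario: str, models, reps: int,
                  mcmc: McmcConfig | None = None, seed: int = 0,
                  out_dir: str | Path | None = None) -> BenchmarkReport:
    """Simulate ``reps`` replicates and benchmark every model on each.

    Per-replicate estimates are written to ``out_dir`` (TSV) when given and
    reloaded on rerun, making long benchmarks resumable; failures are
    counted and excluded.  Fully deterministic given ``seed``.
    """
    models = list(models)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    mcmc = mcmc or McmcConfig()
    cfg = make_scenario(scenario, replicates=reps)
    master = np.random.SeedSequence(seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    estimates: dict[str, list[np.ndarray]] = {m: [] for m in models}
    seeds, failures = [], 0
    truth = None
    for rep, child in enumerate(master.spawn(reps)):
        data, truth = simulate_dataset(cfg, seed=child)
        rep_seed = int(child.generate_state(1)[0] >> 1)
        seeds.append(rep_seed)
        cache = (out_dir / f"{scenario}_rep{rep:03d}.tsv"
                 if out_dir is not None else None)
        if cache is not None and cache.exists():
            df = pd.read_csv(cache, sep="\t", float_precision="round_trip")
        else:
            rows = []
            rng = np.random.default_rng(rep_seed + 1)
            for m in models:
                try:
                    beta = _fit_one(m, data, truth, mcmc, rep_seed, rng)
                except Exception as e:     # noqa: BLE001 — logged, excluded
                    failures += 1
                    print(f"[benchmark] rep {rep} model {m} failed: {e}")
                    continue
                for s in range(2):
                    for p in range(beta.shape[1]):
                        rows.append((m, s, p, beta[s, p]))
            df = pd.DataFrame(rows, columns=["model", "site", "p", "estimate"])
            if cache is not None:
                # %.17g round-trips float64 exactly: resumed runs are
                # byte-identical to fresh ones
                df.to_csv(cache, sep="\t", index=False, float_format="%.17g")
        for m in models:
            sub = df[df.model == m]
            if len(sub):
                beta = sub.pivot(index="site", columns="p",
                                 values="estimate").to_numpy()
                estimates[m].append(beta)

    mse = coefficient_mse({m: np.array(v) for m, v in estimates.items() if v},
                          truth["beta"])
    return BenchmarkReport(scenario=scenario, models=models, replicates=reps,
                           mse=mse, seeds=seeds, runtime_s=time.time() - t0,
                           failures=failures)
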