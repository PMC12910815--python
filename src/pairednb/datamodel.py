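"""Core containers and plain-text I/O for paired two-site count data.

The unit of modeling is a single taxon: counts ``y[s, i]`` for body site
``s`` (0/1 internally, 1/2 in user-facing output) and sample ``i``, with a
per-cell sequencing depth ``N[s, i]`` entering the model as an offset, a
shared covariate matrix ``X`` (first column an intercept), and an optional
group label per sample.  Unbalanced designs are carried with a boolean
presence mask; absent cells contribute nothing to the likelihood.

On disk, count tables are tab-separated with taxa in rows and samples in
columns (a reader option accepts the transpose), and depths are recomputed
at load time as per-sample column sums over the taxa in the file (or an
explicit taxon subset) rather than trusted from metadata.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedCountData",
    "PairedCountTable",
    "ModelSpec",
    "McmcConfig",
    "PosteriorDraws",
    "read_paired_table",
    "read_count_table",
    "write_count_table",
    "write_posterior_summary",
    "MODELS",
]

MODELS = ("SNBM", "JNBM", "JNBM_SG", "JNBM_Mix")


@dataclass
class PairedCountData:
    """Counts for one taxon across two sites with offsets and covariates.

    Attributes
    ----------
    counts : (2, n) int array
    depths : (2, n) int array
        Per-cell sequencing depth (offset); >= 1 wherever present.
    covariates : (n, P) float array, first column all ones.
    group_labels : optional (n,) int array with contiguous labels 1..L_obs.
    present : (2, n) bool array; False marks cells absent from the design.
    sample_ids, taxon : bookkeeping.
    """

    counts: np.ndarray
    depths: np.ndarray
    covariates: np.ndarray
    group_labels: np.ndarray | None = None
    present: np.ndarray | None = None
    sample_ids: list[str] | None = None
    taxon: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.depths = np.asarray(self.depths, dtype=np.int64)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.present is None:
            self.present = np.ones_like(self.counts, dtype=bool)
        else:
            self.present = np.asarray(self.present, dtype=bool)
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels, dtype=np.int64)
        if self.sample_ids is None:
            self.sample_ids = [f"S{i + 1}" for i in range(self.n)]
        self.validate()

    @property
    def n(self) -> int:
        return self.counts.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_groups(self) -> int:
        if self.group_labels is None:
            return 0
        return int(self.group_labels.max())

    def validate(self) -> None:
        if self.counts.shape != self.depths.shape or self.counts.ndim != 2 \
                or self.counts.shape[0] != 2:
            raise ValueError("counts and depths must both be (2, n) arrays")
        n = self.n
        if n < 2:
            raise ValueError("need at least two samples")
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows must match the sample count")
        if not np.allclose(self.covariates[:, 0], 1.0):
            raise ValueError("first covariate column must be an intercept of ones")
        if np.any(~np.isfinite(self.covariates)):
            raise ValueError("covariates contain missing/non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        p = self.present
        if np.any(self.depths[p] < 1):
            raise ValueError("depths must be >= 1 for present cells")
        if np.any(self.counts[p] > self.depths[p]):
            raise ValueError("count exceeds its sample's sequencing depth")
        if self.group_labels is not None:
            g = self.group_labels
            if g.shape != (n,):
                raise ValueError("group labels must be one per sample")
            labels = np.unique(g)
            if not np.array_equal(labels, np.arange(1, labels.size + 1)):
                raise ValueError("group labels must form a contiguous set 1..L")

    def fingerprint(self) -> str:
        """SHA-256 over counts, depths, mask and covariates."""
        h = hashlib.sha256()
        for a in (self.counts, self.depths, self.present,
                  np.ascontiguousarray(self.covariates)):
            h.update(np.ascontiguousarray(a).tobytes())
        if self.group_labels is not None:
            h.update(self.group_labels.tobytes())
        return h.hexdigest()

    def replace(self, **kw) -> "PairedCountData":
        return dataclasses.replace(self, **kw)


@dataclass
class PairedCountTable:
    """Full taxa-by-sample tables for both sites plus sample metadata.

    ``counts[s]`` is a (K, n) array over the union of sample IDs; cells for
    samples absent from a site's file are masked.  Depths are column sums.
    """

    counts: np.ndarray          # (2, K, n)
    taxa: list[str]
    sample_ids: list[str]
    covariates: np.ndarray      # (n, P)
    present: np.ndarray         # (2, n)
    group_labels: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def depths(self, depth_taxa: Sequence[str] | None = None) -> np.ndarray:
        """(2, n) per-sample depths: column sums over all (or a subset of) taxa."""
        if depth_taxa is None:
            sub = self.counts
        else:
            idx = [self.taxa.index(t) for t in depth_taxa]
            sub = self.counts[:, idx, :]
        return sub.sum(axis=1)

    def taxon(self, taxon_id: str,
              depth_taxa: Sequence[str] | None = None) -> PairedCountData:
        if taxon_id not in self.taxa:
            raise KeyError(f"unknown taxon {taxon_id!r}")
        k = self.taxa.index(taxon_id)
        depths = self.depths(depth_taxa)
        present = self.present & (depths >= 1)
        return PairedCountData(
            counts=self.counts[:, k, :],
            depths=np.maximum(depths, 1),
            covariates=self.covariates,
            group_labels=self.group_labels,
            present=present,
            sample_ids=list(self.sample_ids),
            taxon=taxon_id,
        )

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.counts).tobytes())
        h.update(np.ascontiguousarray(self.present).tobytes())
        h.update(np.ascontiguousarray(self.covariates).tobytes())
        return h.hexdigest()


@dataclass
class McmcConfig:
    iterations: int = 20_000
    burnin: int = 10_000
    thin: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burnin < self.iterations):
            raise ValueError("burn-in must be < total iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class ModelSpec:
    """Which model to fit and with what priors and MCMC settings.

    Hyperparameters are the rates of the exponential priors on the
    dispersion alpha_s, the latent-factor variance phi^2 (per component for
    the mixture models), and the coefficient-prior variance tau^2_s;
    defaults (1, 0.1, 0.001).
    """

    model: str = "JNBM"
    L: int = 1
    a_alpha: float = 1.0
    a_phi2: float = 0.1
    a_tau2: float = 0.001
    p_nu: np.ndarray | None = None
    mcmc: McmcConfig = field(default_factory=McmcConfig)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.model == "JNBM_Mix" and self.L < 2:
            raise ValueError("JNBM_Mix needs L > 1")
        for name in ("a_alpha", "a_phi2", "a_tau2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.p_nu is None:
            self.p_nu = np.full(self.L, 1.0 / self.L)
        else:
            self.p_nu = np.asarray(self.p_nu, dtype=float)
            if self.p_nu.shape != (self.L,) or np.any(self.p_nu <= 0):
                raise ValueError("p_nu must be L positive concentrations")


@dataclass
class PosteriorDraws:
    """Retained MCMC draws.  ``beta`` is (B, 2, P); ``phi2`` is (B,) for
    JNBM and (B, L) for the group/mixture models; ``gamma``/``nu``/``xi``
    are None where the model has no such block."""

    beta: np.ndarray
    alpha: np.ndarray
    tau2: np.ndarray
    gamma: np.ndarray | None = None
    phi2: np.ndarray | None = None
    nu: np.ndarray | None = None
    xi: np.ndarray | None = None
    model: str = "JNBM"

    @property
    def B(self) -> int:
        return self.beta.shape[0]

    def check(self) -> None:
        if self.B < 1:
            raise ValueError("empty trace")
        if np.any(self.alpha <= 0) or np.any(self.tau2 <= 0):
            raise ValueError("alpha and tau^2 must be positive in every draw")
        if self.phi2 is not None:
            if np.any(self.phi2 < 0):
                raise ValueError("phi^2 must be non-negative")
            if self.phi2.ndim == 2 and self.phi2.shape[1] > 1:
                if np.any(np.diff(self.phi2, axis=1) <= 0):
                    raise ValueError("mixture variances must be ordered")
        if self.nu is not None and not np.allclose(self.nu.sum(axis=1), 1.0):
            raise ValueError("nu must sum to one")

    def flat(self) -> dict[str, np.ndarray]:
        """Scalar traces keyed by user-facing (1-based) parameter names."""
        out: dict[str, np.ndarray] = {}
        B, S, P = self.beta.shape
        for s in range(S):
            for p in range(P):
                out[f"beta[{s + 1},{p + 1}]"] = self.beta[:, s, p]
            out[f"alpha[{s + 1}]"] = self.alpha[:, s]
            out[f"tau2[{s + 1}]"] = self.tau2[:, s]
        if self.phi2 is not None:
            if self.phi2.ndim == 1:
                out["phi2"] = self.phi2
            else:
                for l in range(self.phi2.shape[1]):
                    out[f"phi2[{l + 1}]"] = self.phi2[:, l]
        if self.nu is not None:
            for l in range(self.nu.shape[1]):
                out[f"nu[{l + 1}]"] = self.nu[:, l]
        if self.gamma is not None:
            for i in range(self.gamma.shape[1]):
                out[f"gamma[{i + 1}]"] = self.gamma[:, i]
        return out


# ---------------------------------------------------------------------------
# I/O

def read_count_table(path, transpose: bool = False) -> pd.DataFrame:
    """Read a tab-separated count table, taxa in rows and samples in columns
    (set ``transpose=True`` for the samples-in-rows layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if transpose:
        df = df.T
    if df.isna().any().any():
        raise ValueError(f"missing values in count table {path}")
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number) or np.any(vals < 0) \
            or np.any(vals != np.floor(vals)):
        raise ValueError(f"count table {path} must hold non-negative integers")
    return df.astype(np.int64)


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_paired_table(count_path_site1, count_path_site2, metadata_path,
                      taxon_id: str, covariate_columns: Sequence[str] | None = None,
                      group_column: str | None = None, transpose: bool = False,
                      depth_taxa: Sequence[str] | None = None) -> PairedCountData:
    """Load one taxon's paired counts from two count tables plus metadata.

    Samples are the union of the two tables' sample IDs; a sample missing
    from one site's table gets presence mask False there.  Metadata must
    have one row per sample (index = sample ID).  Covariate columns get an
    intercept column prepended; with ``covariate_columns=None`` every
    numeric metadata column except the group column is used.
    """
    t1 = read_count_table(count_path_site1, transpose=transpose)
    t2 = read_count_table(count_path_site2, transpose=transpose)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    samples = list(dict.fromkeys([*t1.columns.astype(str), *t2.columns.astype(str)]))
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    taxa = sorted(set(t1.index) | set(t2.index))
    if taxon_id not in taxa:
        raise KeyError(f"unknown taxon {taxon_id!r}")

    K, n = len(taxa), len(samples)
    counts = np.zeros((2, K, n), dtype=np.int64)
    present = np.zeros((2, n), dtype=bool)
    for s, t in enumerate((t1, t2)):
        sub = t.reindex(index=taxa, fill_value=0)
        cols = [c for c in samples if c in t.columns.astype(str)]
        idx = [samples.index(c) for c in cols]
        counts[s][:, idx] = sub[cols].to_numpy()
        present[s, idx] = True

    meta = meta.loc[samples]
    if covariate_columns is None:
        covariate_columns = [c for c in meta.columns
                             if c != group_column
                             and pd.api.types.is_numeric_dtype(meta[c])]
    X = np.column_stack([np.ones(n)] +
                        [meta[c].to_numpy(dtype=float) for c in covariate_columns])
    groups = None
    if group_column is not None:
        raw = meta[group_column]
        codes = pd.Categorical(raw).codes
        if np.any(codes < 0):
            raise ValueError(f"missing group labels in column {group_column!r}")
        groups = codes.astype(np.int64) + 1

    table = PairedCountTable(counts=counts, taxa=taxa, sample_ids=samples,
                             covariates=X, present=present, group_labels=groups)
    return table.taxon(taxon_id, depth_taxa=depth_taxa)


def write_posterior_summary(draws: PosteriorDraws, path) -> pd.DataFrame:
    """Write per-parameter posterior mean, SD and central 95% interval (TSV).

    Deterministic given the draws; returns the summary frame."""
    draws.check()
    rows = []
    for name, trace in draws.flat().items():
        lo, hi = np.percentile(trace, [2.5, 97.5])
        rows.append((name, float(np.mean(trace)), float(np.std(trace, ddof=0)),
                     float(lo), float(hi)))
    out = pd.DataFrame(rows, columns=["parameter", "mean", "sd", "q2.5", "q97.5"])
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return out
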