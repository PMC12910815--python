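"""Evaluation statistics: coefficient MSE tables, DAR residual differences,
and Kullback-Leibler divergence residuals on predicted compositions."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["coefficient_mse", "dar", "kl_residual"]


def coefficient_mse(estimates: dict[str, np.ndarray], truth: np.ndarray,
                    covariates=(1, 2)) -> pd.DataFrame:
    """MSE of posterior-mean regression coefficients over replicates.

    Parameters
    ----------
    estimates : mapping model name -> (reps, 2, P) array of posterior means.
    truth : (2, P) true coefficients.
    covariates : 0-based coefficient indices to tabulate (default the two
        non-intercept covariates; the intercept is excluded by contract).

    Returns a tidy frame with columns model, site (1-based), covariate
    (1-based), mse, se, reps; se = sd(squared errors)/sqrt(reps).
    """
    truth = np.asarray(truth, dtype=float)
    rows = []
    for model, est in estimates.items():
        est = np.asarray(est, dtype=float)
        if est.ndim != 3 or est.shape[1:] != truth.shape:
            raise ValueError(f"estimates for {model!r} must be "
                             f"(reps, {truth.shape[0]}, {truth.shape[1]})")
        reps = est.shape[0]
        sq = (est - truth[None]) ** 2
        for s in range(truth.shape[0]):
            for p in covariates:
                e2 = sq[:, s, p]
                se = float(e2.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
                rows.append((model, s + 1, p + 1, float(e2.mean()), se, reps))
    return pd.DataFrame(rows, columns=["model", "site", "covariate",
                                       "mse", "se", "reps"])


def _relative_abundance(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, counts / tot, np.nan)


def dar(observed: np.ndarray, predicted_a: np.ndarray,
        predicted_b: np.ndarray) -> np.ndarray:
    """Difference of absolute relative-abundance residuals, |r_A| - |r_B|.

    Inputs are (n_samples, K) count/prediction matrices for one site.  The
    residual r^M = y/sum_k y - yhat^M/sum_k yhat^M per cell; positive DAR
    favors model B.  Samples with zero observed total are skipped (NaN row)
    with a warning.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    pa = np.atleast_2d(np.asarray(predicted_a, dtype=float))
    pb = np.atleast_2d(np.asarray(predicted_b, dtype=float))
    if not obs.shape == pa.shape == pb.shape:
        raise ValueError("observed and predicted matrices must align")
    p_obs = _relative_abundance(obs)
    if np.any(np.isnan(p_obs[:, 0])):
        warnings.warn("samples with zero observed total skipped in DAR")
    ra = np.abs(p_obs - _relative_abundance(pa))
    rb = np.abs(p_obs - _relative_abundance(pb))
    return ra - rb


def kl_residual(observed: np.ndarray, predicted: np.ndarray,
                constant: float = 0.1) -> np.ndarray:
    """Per-sample K-L divergence of observed from predicted composition.

    D_i = sum_k p_ik log(p_ik / q_ik) with p the observed relative
    abundances and q the predicted ones after adding ``constant`` (default
    0.1) to every predicted count — the guard for recalculated-depth-zero
    predictions.  Terms with p_ik = 0 contribute 0.
    """
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    pred = np.atleast_2d(np.asarray(predicted, dtype=float)) + constant
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted matrices must align")
    if obs.shape[1] < 2:
        raise ValueError("need at least two taxa for a composition")
    if np.any(obs.sum(axis=1) <= 0):
        raise ValueError("observed row sums must be positive")
    if np.any(pred.sum(axis=1) <= 0):
        raise ValueError("predicted row sums must be positive")
    p = obs / obs.sum(axis=1, keepdims=True)
    q = pred / pred.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
    return terms.sum(axis=1)
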