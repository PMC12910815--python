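import numpy as np
import pytest

from pairednb.datamodel import PairedCountData


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_paired(counts1, counts2, depths1, depths2, X=None, present=None,
                groups=None):
    counts = np.array([counts1, counts2])
    depths = np.array([depths1, depths2])
    n = counts.shape[1]
    if X is None:
        X = np.ones((n, 1))
    return PairedCountData(counts=counts, depths=depths, covariates=X,
                           present=present, group_labels=groups)


@pytest.fixture
def tiny_data():
    """n=3, intercept-only, both sites present."""
    return make_paired([0, 3, 12], [1, 0, 7], [10, 20, 50], [15, 25, 40])


def grid_posterior_mean(log_target, grid):
    """Mean of a 1-D posterior evaluated on a grid (trapezoid weights)."""
    lp = np.array([log_target(v) for v in grid])
    lp -= lp.max()
    w = np.exp(lp)
    z = np.trapezoid(w, grid)
    return np.trapezoid(w * grid, grid) / z


def batch_mean_se(trace, n_batches=40):
    """MC standard error of the mean of a correlated chain via batch means."""
    trace = np.asarray(trace)
    m = len(trace) // n_batches
    b = trace[:m * n_batches].reshape(n_batches, m).mean(axis=1)
    return b.std(ddof=1) / np.sqrt(n_batches)
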