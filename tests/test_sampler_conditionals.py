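"""Each Gibbs conditional against an independent brute-force oracle.

Two layers: (i) the analytic Gaussian conditionals given the PG
auxiliaries are compared with numerical quadrature of the augmented-model
density; (ii) mini-Gibbs chains that alternate only one block with its
auxiliaries are compared with the 1-D grid posterior of the *exact*
(non-augmented) NB model, which validates the augmentation end to end.
"""

import numpy as np
import pytest

from conftest import batch_mean_se, grid_posterior_mean, make_paired
from pairednb.datamodel import McmcConfig, ModelSpec
from pairednb.sampler import (AugmentedState, alpha_log_target,
                              beta_conditional, gamma_conditional, nb_logpmf,
                              update_alpha, update_beta, update_gamma,
                              update_mixture, update_omega,
                              update_variance_hyper, variance_log_target)


def _state_for(data, beta=None, alpha=(1.0, 1.0), gamma=None, tau2=(4.0, 4.0),
               phi2=None):
    n, P = data.n, data.n_covariates
    st = AugmentedState(
        beta=np.zeros((2, P)) if beta is None else np.array(beta, dtype=float),
        alpha=np.array(alpha, dtype=float),
        gamma=np.zeros(n) if gamma is None else np.array(gamma, dtype=float),
        tau2=np.array(tau2, dtype=float),
        phi2=None if phi2 is None else np.atleast_1d(np.asarray(phi2, float)),
        comp=None if phi2 is None else np.zeros(n, dtype=int),
        nu=None, omega=np.zeros((2, n)))
    return st


@pytest.fixture
def one_site_data():
    """n=3 intercept-only data observed at site 1 only."""
    present = np.array([[True, True, True], [False, False, False]])
    return make_paired([0, 3, 12], [0, 0, 0], [10, 20, 50], [1, 1, 1],
                       present=present)


def test_beta_conditional_matches_augmented_quadrature(one_site_data, rng):
    """Given omega, the analytic normal conditional for the intercept equals
    quadrature of exp(sum kappa psi - omega psi^2/2) x N(-tau^2/2, tau^2)."""
    data = one_site_data
    st = _state_for(data)
    update_omega(st, data, 0, rng)
    mean, cov = beta_conditional(st, data, 0)
    r = 1.0
    kappa = (data.counts[0] - r) / 2.0
    off = np.log(data.depths[0])

    def log_target(b):
        psi = off + b
        return float(np.sum(kappa * psi - st.omega[0] * psi**2 / 2.0)
                     - (b + 2.0) ** 2 / 8.0)   # N(-2, 4) prior

    grid = np.linspace(-20, 5, 6001)
    gmean = grid_posterior_mean(log_target, grid)
    assert abs(mean[0] - gmean) < 1e-6
    lp = np.array([log_target(b) for b in grid])
    w = np.exp(lp - lp.max())
    gvar = np.trapezoid(w * (grid - gmean) ** 2, grid) / np.trapezoid(w, grid)
    assert np.isclose(cov[0, 0], gvar, rtol=1e-6)


def test_beta_marginal_matches_exact_nb_grid(one_site_data, rng):
    """Alternating omega | beta and beta | omega targets the exact NB
    posterior: long-run mean within 3 batch-mean SEs of the grid oracle."""
    data = one_site_data
    st = _state_for(data)

    def log_target(b):
        mu = data.depths[0] * np.exp(b)
        return float(np.sum(nb_logpmf(data.counts[0], mu, 1.0))
                     - (b + 2.0) ** 2 / 8.0)

    gmean = grid_posterior_mean(log_target, np.linspace(-20, 5, 6001))
    trace = np.empty(40_000)
    for it in range(42_000):
        update_omega(st, data, 0, rng)
        update_beta(st, data, 0, rng)
        if it >= 2_000:
            trace[it - 2_000] = st.beta[0, 0]
    se = batch_mean_se(trace)
    assert abs(trace.mean() - gmean) < 3 * se + 0.01


def test_beta_prior_limit_no_data(rng):
    """With every cell at a site masked, update_beta draws from the prior."""
    present = np.array([[False] * 4, [True] * 4])
    data = make_paired([0] * 4, [1, 2, 3, 4], [1] * 4, [9] * 4,
                       present=present)
    st = _state_for(data, tau2=(4.0, 4.0))
    draws = np.empty(4000)
    for b in range(4000):
        update_beta(st, data, 0, rng)
        draws[b] = st.beta[0, 0]
    assert abs(draws.mean() - (-2.0)) < 4 * 2.0 / np.sqrt(4000)
    assert np.isclose(draws.var(), 4.0, rtol=0.15)


def test_beta_gls_limit_large_prior_variance(one_site_data, rng):
    """As tau^2 -> inf with omega fixed, the conditional mean approaches the
    generalized-least-squares solution of the augmented Gaussian model.

    Because the prior is N(-tau^2/2, tau^2), its contribution to the
    normal equations is a constant -1/2 per coordinate that does *not*
    vanish in the limit (mean and variance are coupled); the limit is the
    GLS solution of X'Omega X b = X'Omega z - 1/2, which differs from the
    plain weighted-least-squares fit by exactly that shrinkage term.
    """
    data = one_site_data
    st = _state_for(data, tau2=(1e12, 1e12))
    update_omega(st, data, 0, rng)
    mean, _ = beta_conditional(st, data, 0)
    r = 1.0
    kappa = (data.counts[0] - r) / 2.0
    z = kappa / st.omega[0] - np.log(data.depths[0])
    sw = np.sum(st.omega[0])
    gls = (np.sum(st.omega[0] * z) - 0.5) / sw
    wls = np.sum(st.omega[0] * z) / sw
    assert abs(mean[0] - gls) < 1e-4
    assert np.isclose(wls - gls, 0.5 / sw)


def test_gamma_marginal_matches_exact_nb_grid(rng):
    """Latent-factor mini-Gibbs (omega, gamma alternation) agrees with the
    exact 1-cell NB grid posterior; the data-free sample's conditional is
    its prior."""
    present = np.array([[True, False], [False, False]])
    data = make_paired([7, 0], [0, 0], [40, 1], [1, 1], present=present)
    phi2 = 1.5
    st = _state_for(data, beta=[[-1.0], [0.0]], phi2=phi2)

    def log_target(g):
        mu = 40 * np.exp(g - 1.0)
        return float(nb_logpmf(7.0, mu, 1.0)
                     - (g + phi2 / 2) ** 2 / (2 * phi2))

    gmean = grid_posterior_mean(log_target, np.linspace(-8, 6, 4001))
    trace = np.empty(40_000)
    for it in range(42_000):
        update_omega(st, data, 0, rng)
        update_gamma(st, data, rng)
        if it >= 2_000:
            trace[it - 2_000] = st.gamma[0]
    assert abs(trace.mean() - gmean) < 3 * batch_mean_se(trace) + 0.01
    # sample 2 is absent from both sites: conditional == prior
    mean, var = gamma_conditional(st, data)
    assert np.isclose(mean[1], -phi2 / 2)
    assert np.isclose(var[1], phi2)


def test_gamma_degenerate_prior_pins_at_zero(tiny_data):
    st = _state_for(tiny_data, phi2=0.0)
    mean, var = gamma_conditional(st, tiny_data)
    assert np.all(mean == 0) and np.all(var == 0)


def test_alpha_mh_matches_grid(rng, tiny_data):
    """Long MH run for the dispersion against the 1-D grid posterior of the
    exact NB likelihood x Exp(1) prior over (0, 50]."""
    data = tiny_data
    st = _state_for(data, beta=[[-2.0], [-2.0]])

    def log_target(a):
        return alpha_log_target(a, st, data, 0, 1.0)

    gmean = grid_posterior_mean(log_target, np.linspace(1e-3, 50, 8001))
    trace = np.empty(60_000)
    for it in range(64_000):
        update_alpha(st, data, 0, rng, 1.0)
        if it >= 4_000:
            trace[it - 4_000] = st.alpha[0]
    assert abs(trace.mean() - gmean) < 3 * batch_mean_se(trace) + 0.02


def test_alpha_prior_limit_no_data(rng):
    """With no observed cells the MH chain targets Exp(a): long-run mean
    1/a."""
    present = np.array([[False] * 3, [True] * 3])
    data = make_paired([0] * 3, [1, 1, 1], [1] * 3, [5] * 3, present=present)
    st = _state_for(data)
    trace = np.empty(40_000)
    for it in range(42_000):
        update_alpha(st, data, 0, rng, 2.0)
        if it >= 2_000:
            trace[it - 2_000] = st.alpha[0]
    assert abs(trace.mean() - 0.5) < 3 * batch_mean_se(trace) + 0.01


def test_variance_hyper_mh_matches_grid(rng):
    """phi^2 MH long-run mean against the grid posterior for 5 fixed
    latent values under the N(-v/2, v) x Exp(0.1) target."""
    governed = np.array([-0.7, 0.3, 1.9, -2.2, 0.5])

    def log_target(v):
        return variance_log_target(v, governed, 0.1)

    gmean = grid_posterior_mean(log_target, np.linspace(1e-3, 60, 8001))
    v, trace = 1.0, np.empty(60_000)
    for it in range(64_000):
        v, _ = update_variance_hyper(v, governed, 0.1, 0.6, rng)
        if it >= 4_000:
            trace[it - 4_000] = v
    assert abs(trace.mean() - gmean) < 3 * batch_mean_se(trace) + 0.02


def test_variance_hyper_empty_block_prior_mean(rng):
    """Empty governed block without constraint: exact Exp(a) draws."""
    draws = np.array([update_variance_hyper(1.0, np.empty(0), 4.0, 0.5,
                                            rng)[0] for _ in range(20_000)])
    assert abs(draws.mean() - 0.25) < 4 * 0.25 / np.sqrt(20_000)


def test_variance_hyper_empty_block_respects_interval(rng):
    draws = np.array([update_variance_hyper(1.0, np.empty(0), 0.5, 0.5, rng,
                                            lo=2.0, hi=3.0)[0]
                      for _ in range(500)])
    assert np.all((draws > 2.0) & (draws < 3.0))


def test_variance_hyper_order_violations_rejected(rng):
    """Any proposal outside (lo, hi) is rejected with probability 1."""
    governed = np.array([0.1, -0.3])
    for _ in range(400):
        v, acc = update_variance_hyper(1.0, governed, 0.1, 2.0, rng,
                                       lo=0.5, hi=1.4)
        assert 0.5 < v < 1.4


def test_mixture_allocation_probabilities(rng):
    """gamma=0, phi^2=(0.5, 10), nu=(1/2, 1/2): allocation follows the two
    normal densities, strongly favoring the tight component."""
    from scipy.stats import norm
    data = make_paired([1, 1], [1, 1], [5, 5], [5, 5])
    st = _state_for(data, phi2=[0.5, 10.0])
    st.nu = np.array([0.5, 0.5])
    st.comp = np.zeros(2, dtype=int)
    st.gamma = np.zeros(2)
    d1 = norm.pdf(0, -0.25, np.sqrt(0.5))
    d2 = norm.pdf(0, -5.0, np.sqrt(10.0))
    p1 = d1 / (d1 + d2)
    hits = 0
    reps = 3000
    for _ in range(reps):
        st.nu = np.array([0.5, 0.5])
        update_mixture(st, np.array([0.5, 0.5]), rng)
        hits += np.sum(st.comp == 0)
    frac = hits / (2 * reps)
    assert p1 > 0.9            # sanity on the oracle itself (p1 ~ 0.937)
    assert abs(frac - p1) < 0.01


def test_mixture_equal_variances_follow_weights(rng):
    """With all phi^2_l equal the likelihood cancels and allocation
    probabilities equal nu."""
    data = make_paired([1, 1], [1, 1], [5, 5], [5, 5])
    st = _state_for(data, phi2=[2.0, 2.0])
    st.comp = np.zeros(2, dtype=int)
    st.gamma = np.array([0.3, -1.0])
    hits = 0
    reps = 4000
    for _ in range(reps):
        st.nu = np.array([0.3, 0.7])
        update_mixture(st, np.array([0.5, 0.5]), rng)
        hits += np.sum(st.comp == 0)
    assert abs(hits / (2 * reps) - 0.3) < 0.02


def test_mixture_single_component_trivial(rng):
    data = make_paired([1, 1], [1, 1], [5, 5], [5, 5])
    st = _state_for(data, phi2=[2.0])
    st.comp = np.ones(2, dtype=int)
    st.nu = np.array([1.0])
    update_mixture(st, np.array([1.0]), rng)
    assert np.all(st.comp == 0) and st.nu[0] == 1.0
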