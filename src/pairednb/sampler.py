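"""Pólya-Gamma-augmented Gibbs sampler for the joint NB latent factor models.

Model (per taxon): counts y[s,i] ~ NB(mu[s,i], alpha_s) with mean
mu = exp(gamma_i + log N[s,i] + x_i' beta_s) and variance (1 + mu alpha) mu.
The shared latent factor gamma_i ~ N(-phi^2/2, phi^2) is the sole source of
cross-site correlation (gamma_i = 0 under SNBM; component- or group-specific
phi^2_l under JNBM_Mix / JNBM_SG).  Priors: beta_sp ~ N(-tau^2_s/2, tau^2_s),
and independent exponentials on (alpha_s, phi^2, tau^2_s).

Augmentation: writing the NB mass with stopping parameter r = 1/alpha and
logistic tilt psi = log(mu / r),

    NB(y | mu, alpha)  propto  exp(kappa psi) E_omega exp(-omega psi^2 / 2),
    kappa = (y - r) / 2,     omega ~ PG(y + r, psi),

so given omega the likelihood is Gaussian in (beta, gamma) and those blocks
have closed-form normal full conditionals.  The dispersion and the
variance hyperparameters (whose N(-v/2, v) prior couples mean and variance
and breaks inverse-gamma conjugacy) are updated by adaptive log-scale
random-walk Metropolis targeting the exact conditionals.

Sweep order: omega -> beta_1, beta_2 -> gamma -> alpha_1, alpha_2 ->
phi^2 block (-> mixture allocations and weights) -> tau^2_1, tau^2_2.

RNG discipline: one master seed spawns three child streams (site 1, site 2,
shared).  Site-specific blocks draw only from their site's stream, so under
SNBM the two sites' traces are independent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .datamodel import McmcConfig, ModelSpec, PairedCountData, PosteriorDraws
from .pg import pg_draw

__all__ = [
    "AugmentedState", "run_gibbs", "nb_logpmf",
    "update_omega", "update_beta", "update_gamma", "update_alpha",
    "update_variance_hyper", "update_mixture",
    "beta_conditional", "gamma_conditional",
    "alpha_log_target", "variance_log_target",
]

PSI_CLIP = 30.0
_ADAPT_EVERY = 50
_TARGET_ACC = 0.44


def nb_logpmf(y, mu, alpha):
    """log NB(y | mean mu, dispersion alpha); alpha = 0 is the Poisson limit."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if np.isscalar(alpha) and alpha == 0:
        return y * np.log(mu) - mu - gammaln(y + 1)
    r = 1.0 / alpha
    return (gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * (np.log(r) - np.log(r + mu))
            + y * (np.log(mu) - np.log(r + mu)))


@dataclass
class AugmentedState:
    """Current values of all parameter blocks plus the PG auxiliaries.

    ``phi2`` has length 1 for JNBM and length L for the group/mixture
    models; ``comp[i]`` maps sample i to its variance component (all zeros
    for JNBM, fixed g(i)-1 for JNBM_SG, resampled xi_i-1 for JNBM_Mix).
    """

    beta: np.ndarray            # (2, P)
    alpha: np.ndarray           # (2,)
    gamma: np.ndarray           # (n,)
    tau2: np.ndarray            # (2,)
    phi2: np.ndarray | None     # (L,) or None under SNBM
    comp: np.ndarray | None     # (n,) int component index, or None
    nu: np.ndarray | None       # (L,) mixture weights (JNBM_Mix)
    omega: np.ndarray           # (2, n) PG auxiliaries (0 at absent cells)
    step_alpha: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    step_phi2: np.ndarray | None = None
    step_tau2: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    acc_alpha: np.ndarray = field(default_factory=lambda: np.zeros(2))
    acc_phi2: np.ndarray | None = None
    acc_tau2: np.ndarray = field(default_factory=lambda: np.zeros(2))
    log_depths: np.ndarray | None = None   # cached log N, set by run_gibbs

    def logN(self, data: PairedCountData) -> np.ndarray:
        if self.log_depths is None:
            self.log_depths = np.log(data.depths)
        return self.log_depths

    def psi(self, data: PairedCountData, s: int) -> np.ndarray:
        """Linear predictor in logistic form, psi = log(mu) - log(r)."""
        r = 1.0 / self.alpha[s]
        return (self.gamma + self.logN(data)[s] +
                data.covariates @ self.beta[s] - np.log(r))

    def mu(self, data: PairedCountData, s: int) -> np.ndarray:
        return np.exp(self.gamma + self.logN(data)[s] +
                      data.covariates @ self.beta[s])

    def phi2_of_sample(self) -> np.ndarray:
        return self.phi2[self.comp]


# ---------------------------------------------------------------------------
# block updates

def update_omega(state: AugmentedState, data: PairedCountData, s: int,
                 rng: np.random.Generator) -> None:
    """omega[s,i] ~ PG(y + r, psi) for present cells; 0 at absent cells."""
    r = 1.0 / state.alpha[s]
    psi = np.clip(state.psi(data, s), -PSI_CLIP, PSI_CLIP)
    b = data.counts[s] + r
    om = pg_draw(b, psi, rng)
    om[~data.present[s]] = 0.0
    state.omega[s] = om


def _update_omega_joint(state: AugmentedState, data: PairedCountData,
                        rng: np.random.Generator) -> None:
    """Both sites' PG auxiliaries in one vectorized draw (joint models)."""
    r = 1.0 / state.alpha
    psi = np.clip(
        state.gamma[None, :] + state.logN(data)
        + (data.covariates @ state.beta.T).T
        + np.log(state.alpha)[:, None],
        -PSI_CLIP, PSI_CLIP)
    om = pg_draw(data.counts + r[:, None], psi, rng)
    om[~data.present] = 0.0
    state.omega = om


def beta_conditional(state: AugmentedState, data: PairedCountData, s: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the normal full conditional of beta_s.

    Precision = X' Omega X + I / tau^2_s; the linear term collects
    kappa - omega * (gamma + log N - log r) plus the prior's -1/2 per
    coordinate (from mean -tau^2/2, variance tau^2).
    """
    m = data.present[s]
    X = data.covariates[m]
    om = state.omega[s][m]
    r = 1.0 / state.alpha[s]
    kappa = (data.counts[s][m] - r) / 2.0
    off = state.gamma[m] + state.logN(data)[s][m] - np.log(r)
    P = data.n_covariates
    prec = X.T @ (om[:, None] * X) + np.eye(P) / state.tau2[s]
    lin = X.T @ (kappa - om * off) - 0.5 * np.ones(P)
    try:
        cov = np.linalg.inv(prec)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular precision for beta update (collinear covariates?)") from e
    return cov @ lin, cov


def update_beta(state: AugmentedState, data: PairedCountData, s: int,
                rng: np.random.Generator) -> None:
    mean, cov = beta_conditional(state, data, s)
    chol = np.linalg.cholesky(cov)
    state.beta[s] = mean + chol @ rng.standard_normal(mean.size)


def gamma_conditional(state: AugmentedState, data: PairedCountData
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample mean and variance of gamma_i's normal full conditional.

    Combines both sites' augmented Gaussian terms (present cells only) with
    the N(-phi2*/2, phi2*) prior, phi2* component-specific.  Samples whose
    prior variance is 0 get a degenerate (0-variance) conditional at 0.
    """
    v_prior = state.phi2_of_sample()
    zero = v_prior <= 0
    v_safe = np.where(zero, 1.0, v_prior)
    prec = 1.0 / v_safe
    lin = np.full(data.n, -0.5)
    for s in range(2):
        m = data.present[s]
        r = 1.0 / state.alpha[s]
        kappa = (data.counts[s] - r) / 2.0
        off = (state.logN(data)[s] + data.covariates @ state.beta[s]
               - np.log(r))
        prec = prec + np.where(m, state.omega[s], 0.0)
        lin = lin + np.where(m, kappa - state.omega[s] * off, 0.0)
    var = 1.0 / prec
    mean = var * lin
    mean[zero] = 0.0
    var[zero] = 0.0
    return mean, var


def update_gamma(state: AugmentedState, data: PairedCountData,
                 rng: np.random.Generator) -> None:
    mean, var = gamma_conditional(state, data)
    state.gamma = mean + np.sqrt(var) * rng.standard_normal(data.n)


def alpha_log_target(alpha: float, state: AugmentedState,
                     data: PairedCountData, s: int, a_alpha: float) -> float:
    """log p(alpha_s | rest) up to a constant: exact NB likelihood at the
    present cells times the Exp(a_alpha) prior."""
    if alpha <= 0:
        return -np.inf
    m = data.present[s]
    mu = state.mu(data, s)[m]
    ll = np.sum(nb_logpmf(data.counts[s][m], mu, alpha))
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite NB log-likelihood in alpha update")
    return ll - a_alpha * alpha


def _alpha_target_terms(alpha: float, y: np.ndarray, mu: np.ndarray,
                        a_alpha: float) -> float:
    """alpha_log_target minus its alpha-free terms (enough for MH ratios)."""
    r = 1.0 / alpha
    lr_mu = np.log(r + mu)
    return (np.sum(gammaln(y + r)) - y.size * gammaln(r)
            + r * (y.size * np.log(r) - np.sum(lr_mu))
            - np.sum(y * lr_mu) - a_alpha * alpha)


def update_alpha(state: AugmentedState, data: PairedCountData, s: int,
                 rng: np.random.Generator, a_alpha: float) -> bool:
    """One log-scale random-walk MH update of alpha_s; returns acceptance."""
    cur = state.alpha[s]
    prop = cur * np.exp(state.step_alpha[s] * rng.standard_normal())
    m = data.present[s]
    mu = state.mu(data, s)[m]
    y = data.counts[s][m].astype(float)
    # +log(alpha) Jacobian for the log-scale walk
    loga = (_alpha_target_terms(prop, y, mu, a_alpha) + np.log(prop)
            - _alpha_target_terms(cur, y, mu, a_alpha) - np.log(cur))
    if np.isnan(loga):
        raise FloatingPointError("non-finite NB log-likelihood in alpha update")
    if np.log(rng.uniform()) < loga:
        state.alpha[s] = prop
        return True
    return False


def variance_log_target(v: float, governed: np.ndarray, a_v: float) -> float:
    """log of prod_j N(x_j; -v/2, v) * Exp(a_v)(v), up to a constant."""
    if v <= 0:
        return -np.inf
    x = np.asarray(governed, dtype=float)
    k = x.size
    return (-0.5 * k * np.log(2 * np.pi * v)
            - np.sum((x + v / 2.0) ** 2) / (2.0 * v)
            - a_v * v)


def _trunc_exp_draw(a: float, lo: float, hi: float,
                    rng: np.random.Generator) -> float:
    """Exact draw from Exp(a) truncated to (lo, hi) by inverse CDF."""
    clo = np.exp(-a * lo)
    chi = np.exp(-a * hi) if np.isfinite(hi) else 0.0
    u = rng.uniform()
    return -np.log(clo - u * (clo - chi)) / a


def update_variance_hyper(v: float, governed: np.ndarray, a_v: float,
                          step: float, rng: np.random.Generator,
                          lo: float = 0.0, hi: float = np.inf
                          ) -> tuple[float, bool]:
    """MH (log-scale random walk) update of one variance hyperparameter.

    ``governed`` holds the latent values the N(-v/2, v) prior governs
    (gamma_i of the relevant component, or beta_sp for tau^2_s).  With an
    empty governed block the conditional is the Exp(a_v) prior restricted
    to the order-compatible interval (lo, hi) and is drawn exactly.
    Proposals outside (lo, hi) — the JNBM_Mix ordering constraint — are
    rejected.  Returns (new value, accepted flag).
    """
    governed = np.asarray(governed, dtype=float)
    if governed.size == 0:
        return _trunc_exp_draw(a_v, lo, max(lo, min(hi, 1e12)), rng), True
    prop = v * np.exp(step * rng.standard_normal())
    if not (lo < prop < hi):
        return v, False
    loga = (variance_log_target(prop, governed, a_v) + np.log(prop)
            - variance_log_target(v, governed, a_v) - np.log(v))
    if np.log(rng.uniform()) < loga:
        return prop, True
    return v, False


def recenter_gamma(state: AugmentedState, data: PairedCountData,
                   rng: np.random.Generator) -> None:
    """Exact Gibbs move along the likelihood-invariant translation group
    (gamma_i + x_i' delta, beta_s - delta).

    Every mu[s,i] = exp(gamma_i + log N + x_i' beta_s) is unchanged by
    adding x_i' delta to the latent factors while subtracting delta from
    both sites' coefficient vectors, so the P-dimensional shift delta has
    a purely prior-driven Gaussian full conditional.  Without this move
    the chain random-walks along those ridges — the split between a
    covariate trend carried by beta (both sites) and one carried by the
    free per-sample factors is identified only through the priors — and
    the coefficient directions can need orders of magnitude more sweeps.
    The translation has unit Jacobian, so the move targets the exact
    posterior (a generalized-Gibbs group move).
    """
    v = state.phi2_of_sample()
    if np.any(v <= 0):
        return  # degenerate prior pins gamma at 0; shifting would break it
    X = data.covariates
    Xw = X / v[:, None]
    A = X.T @ Xw + np.sum(1.0 / state.tau2) * np.eye(X.shape[1])
    lin = (-Xw.T @ (state.gamma + v / 2.0)
           + np.sum((state.beta + state.tau2[:, None] / 2.0)
                    / state.tau2[:, None], axis=0))
    cov = np.linalg.inv(A)
    delta = cov @ lin + np.linalg.cholesky(cov) @ rng.standard_normal(
        X.shape[1])
    state.gamma = state.gamma + X @ delta
    state.beta -= delta[None, :]


def update_mixture(state: AugmentedState, p_nu: np.ndarray,
                   rng: np.random.Generator) -> None:
    """Resample allocations xi_i and weights nu (JNBM_Mix only).

    p(xi_i = l | rest) propto nu_l N(gamma_i; -phi2_l/2, phi2_l), computed
    in log space; nu ~ Dirichlet(p_nu + component counts).
    """
    L = state.phi2.size
    if L == 1:
        state.comp = np.zeros_like(state.comp)
        state.nu = np.ones(1)
        return
    g = state.gamma[:, None]
    v = state.phi2[None, :]
    logw = (np.log(state.nu)[None, :]
            - 0.5 * np.log(2 * np.pi * v) - (g + v / 2.0) ** 2 / (2.0 * v))
    logw = logw - logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.uniform(size=g.shape[0])
    state.comp = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
    counts = np.bincount(state.comp, minlength=L)
    state.nu = rng.dirichlet(p_nu + counts)


# ---------------------------------------------------------------------------
# driver

def _init_state(data: PairedCountData, spec: ModelSpec,
                rng_shared: np.random.Generator) -> AugmentedState:
    n, P = data.n, data.n_covariates
    beta = np.zeros((2, P))
    for s in range(2):
        m = data.present[s]
        z = np.log((data.counts[s][m] + 0.5) / data.depths[s][m])
        beta[s], *_ = np.linalg.lstsq(data.covariates[m], z, rcond=None)
    if spec.model == "SNBM":
        phi2, comp, nu = None, None, None
    elif spec.model == "JNBM":
        phi2, comp, nu = np.array([1.0]), np.zeros(n, dtype=int), None
    elif spec.model == "JNBM_SG":
        L = data.n_groups
        phi2 = np.ones(L)
        comp, nu = data.group_labels - 1, None
    else:  # JNBM_Mix: ordered starting values, uniform weights/allocations
        L = spec.L
        phi2 = np.linspace(0.5, 1.5, L)
        comp = rng_shared.integers(0, L, size=n)
        nu = np.full(L, 1.0 / L)
    state = AugmentedState(
        beta=beta, alpha=np.ones(2), gamma=np.zeros(n), tau2=np.ones(2),
        phi2=phi2, comp=comp, nu=nu, omega=np.zeros((2, n)))
    if phi2 is not None:
        state.step_phi2 = np.full(phi2.size, 0.5)
        state.acc_phi2 = np.zeros(phi2.size)
    return state


def _check_finite(state: AugmentedState, it: int) -> None:
    blocks = {"beta": state.beta, "alpha": state.alpha, "gamma": state.gamma,
              "tau2": state.tau2}
    if state.phi2 is not None:
        blocks["phi2"] = state.phi2
    for name, arr in blocks.items():
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError(
                f"non-finite value in block {name!r} at iteration {it}")


def _update_phi2_block(state: AugmentedState, spec: ModelSpec, model: str,
                       rng: np.random.Generator) -> None:
    L = state.phi2.size
    ordered = model == "JNBM_Mix"
    for l in range(L):
        lo = state.phi2[l - 1] if (ordered and l > 0) else 0.0
        hi = state.phi2[l + 1] if (ordered and l < L - 1) else np.inf
        governed = state.gamma[state.comp == l]
        new, acc = update_variance_hyper(
            state.phi2[l], governed, spec.a_phi2, state.step_phi2[l], rng,
            lo=lo, hi=hi)
        state.phi2[l] = new
        state.acc_phi2[l] += acc


def _adapt(step: np.ndarray, acc: np.ndarray) -> None:
    rate = acc / _ADAPT_EVERY
    step *= np.exp(0.66 * (rate - _TARGET_ACC))
    np.clip(step, 1e-3, 10.0, out=step)
    acc[:] = 0.0


def run_gibbs(data: PairedCountData, spec: ModelSpec) -> PosteriorDraws:
    """Run the full Gibbs sweep and return burned-in, thinned draws.

    Fully reproducible given ``spec.mcmc.seed``; a NaN/Inf in any state
    block aborts with the block named.
    """
    data.validate()
    model = spec.model
    if model == "JNBM_SG" and data.group_labels is None:
        raise ValueError("JNBM_SG requires group labels")
    ss = np.random.SeedSequence(spec.mcmc.seed)
    rng_site = [np.random.Generator(np.random.PCG64(c))
                for c in ss.spawn(2)]
    rng_shared = np.random.Generator(np.random.PCG64(ss.spawn(1)[0]))

    state = _init_state(data, spec, rng_shared)
    cfg: McmcConfig = spec.mcmc
    keep = range(cfg.burnin, cfg.iterations, cfg.thin)
    B = len(keep)
    n, P = data.n, data.n_covariates
    L = 0 if state.phi2 is None else state.phi2.size

    out_beta = np.empty((B, 2, P))
    out_alpha = np.empty((B, 2))
    out_tau2 = np.empty((B, 2))
    out_gamma = np.empty((B, n)) if model != "SNBM" else None
    out_phi2 = (np.empty(B) if model == "JNBM" else
                np.empty((B, L)) if L else None)
    out_nu = np.empty((B, L)) if model == "JNBM_Mix" else None
    out_xi = np.empty((B, n), dtype=np.int64) if model == "JNBM_Mix" else None

    b_out = 0
    snbm = model == "SNBM"
    for it in range(cfg.iterations):
        if snbm:
            # per-site streams keep the two sites' chains independent
            for s in range(2):
                update_omega(state, data, s, rng_site[s])
        else:
            _update_omega_joint(state, data, rng_shared)
        for s in range(2):
            update_beta(state, data, s, rng_site[s])
        if model != "SNBM":
            update_gamma(state, data, rng_shared)
            recenter_gamma(state, data, rng_shared)
        for s in range(2):
            state.acc_alpha[s] += update_alpha(state, data, s, rng_site[s],
                                               spec.a_alpha)
        if model != "SNBM":
            _update_phi2_block(state, spec, model, rng_shared)
        if model == "JNBM_Mix":
            update_mixture(state, spec.p_nu, rng_shared)
        for s in range(2):
            new, acc = update_variance_hyper(
                state.tau2[s], state.beta[s], spec.a_tau2,
                state.step_tau2[s], rng_site[s])
            state.tau2[s] = new
            state.acc_tau2[s] += acc

        if it < cfg.burnin and (it + 1) % _ADAPT_EVERY == 0:
            _adapt(state.step_alpha, state.acc_alpha)
            _adapt(state.step_tau2, state.acc_tau2)
            if state.phi2 is not None:
                _adapt(state.step_phi2, state.acc_phi2)
        _check_finite(state, it)

        if it >= cfg.burnin and (it - cfg.burnin) % cfg.thin == 0:
            out_beta[b_out] = state.beta
            out_alpha[b_out] = state.alpha
            out_tau2[b_out] = state.tau2
            if out_gamma is not None:
                out_gamma[b_out] = state.gamma
            if model == "JNBM":
                out_phi2[b_out] = state.phi2[0]
            elif L:
                out_phi2[b_out] = state.phi2
            if model == "JNBM_Mix":
                out_nu[b_out] = state.nu
                out_xi[b_out] = state.comp + 1
            b_out += 1

    draws = PosteriorDraws(beta=out_beta, alpha=out_alpha, tau2=out_tau2,
                           gamma=out_gamma, phi2=out_phi2, nu=out_nu,
                           xi=out_xi, model=model)
    draws.check()
    return draws
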