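"""Posterior computation: MMALA for the level-set coefficients within Gibbs.

One systematic scan updates, in order,

  1. beta  — a Metropolis-adjusted Langevin step preconditioned by a
     position-dependent metric G(beta) (expected Fisher information of the
     beta-likelihood plus the prior precision), the simplified manifold
     variant of Girolami & Calderhead;
  2. mu    — conjugate normal draws per subject;
  3. eta   — either the spike-and-slab block (eta jointly, then the spike
     indicators gamma element-wise, the inclusion probability w, and the slab
     variances tau_k^2) or the normal-prior block (eta jointly, tau_eta^2);
  4. sigma_i^2 and tau_mu^2 — conjugate inverse-gamma draws.

All conditional updates accept optional precomputed auxiliaries (H, Y H, ...)
so the driver can share them across the scan without a second code path.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .forward_model import (
    ChainState,
    Dataset,
    HyperParams,
    smoothed_heaviside,
    smoothed_heaviside_deriv,
)
from .gp_basis import BasisExpansion

__all__ = [
    "RunConfig",
    "PosteriorDraws",
    "MMALATuning",
    "update_beta",
    "update_mu",
    "update_eta_ssvs",
    "update_eta_ssvs_collapsed",
    "update_eta_normal",
    "update_variances",
    "initialize_state",
    "run_chain",
]

# Stochastic-approximation acceptance target for the MALA family.
TARGET_ACCEPT = 0.574
ADAPT_GAIN = 0.15
# Voxels with |phi_j| beyond this many eps contribute negligibly to the Fisher
# metric (H'^2 falls off as (eps/x)^4) and are dropped from its assembly.
METRIC_CUT_MULT = 100.0


@dataclass
class RunConfig:
    """MCMC run configuration.

    ``prior_variant`` selects the spike-and-slab ("spike_slab") or plain
    normal ("normal") prior on the genetic effects.  ``metric`` chooses the
    position-dependent Fisher metric ("fisher", default) or a fixed
    prior-precision preconditioner ("fixed") for the beta proposal.
    """

    n_iter: int = 2000
    n_burnin: int = 1000
    thin: int = 2
    step_size: float = 0.1
    prior_variant: str = "spike_slab"
    metric: str = "fisher"
    adapt: bool = True
    anneal_eps0: float = 0.3
    hyper: HyperParams = field(default_factory=HyperParams)
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_burnin < self.n_iter):
            raise ValueError("need 0 <= n_burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not self.step_size > 0:
            raise ValueError("step_size must be positive")
        if self.prior_variant not in ("spike_slab", "normal"):
            raise ValueError(f"unknown prior_variant {self.prior_variant!r}")
        if self.metric not in ("fisher", "fixed"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.anneal_eps0 < 0:
            raise ValueError("anneal_eps0 must be >= 0 (0 disables annealing)")


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in draws plus sampler diagnostics."""

    beta: np.ndarray      # (T, L)
    mu: np.ndarray        # (T, n)
    eta: np.ndarray       # (T, m)
    gamma: np.ndarray     # (T, m)
    w: np.ndarray         # (T,)
    sigma2: np.ndarray    # (T, n)
    tau_mu2: np.ndarray   # (T,)
    tau2: np.ndarray      # (T, m) slab variances (spike-and-slab variant)
    tau_eta2: np.ndarray  # (T,)   shared variance (normal variant)
    accept_rate: float
    step_size: float
    prior_variant: str
    seed: int
    config: dict

    @property
    def n_saved(self) -> int:
        return self.beta.shape[0]

    def to_hdf5(self, path) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as f:
            for name in ("beta", "mu", "eta", "gamma", "w", "sigma2",
                         "tau_mu2", "tau2", "tau_eta2"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["accept_rate"] = self.accept_rate
            f.attrs["step_size"] = self.step_size
            f.attrs["prior_variant"] = self.prior_variant
            f.attrs["seed"] = self.seed
            f.attrs["config"] = json.dumps(self.config)

    @staticmethod
    def from_hdf5(path) -> "PosteriorDraws":
        import h5py
        import json

        with h5py.File(path, "r") as f:
            arrays = {name: f[name][()] for name in
                      ("beta", "mu", "eta", "gamma", "w", "sigma2",
                       "tau_mu2", "tau2", "tau_eta2")}
            return PosteriorDraws(
                **arrays,
                accept_rate=float(f.attrs["accept_rate"]),
                step_size=float(f.attrs["step_size"]),
                prior_variant=str(f.attrs["prior_variant"]),
                seed=int(f.attrs["seed"]),
                config=json.loads(f.attrs["config"]),
            )


@dataclass
class MMALATuning:
    """Mutable tuning state of the beta move."""

    step_size: float = 0.1
    metric: str = "fisher"
    adapt: bool = True
    iteration: int = 0


def _sample_invgamma(rng, shape, rate):
    """Inverse gamma with shape/rate parameterization: density ~ x^{-a-1} e^{-b/x}."""
    return rate / rng.gamma(shape, 1.0, size=np.shape(rate) or None)


class _BetaGeometry:
    """Log-density, gradient and metric Cholesky of the beta conditional at one
    point, with the beta-free likelihood constant dropped.

    Valid only for the (u, c) it was built with: u and c are functions of mu
    and sigma^2, so the geometry must be rebuilt after every Gibbs scan even
    when beta itself did not move.  ``phi`` (= Psi beta) may be passed in when
    already available to save the matrix-vector product.
    """

    __slots__ = ("beta", "phi", "H", "logdens", "grad", "chol", "logdet", "ok")

    def __init__(self, beta, u, c, data, basis, eps, metric, phi=None):
        lam = basis.eigenvalues
        self.beta = beta
        self.phi = basis.Psi @ beta if phi is None else phi
        self.H = smoothed_heaviside(self.phi, eps)
        uH = float(u @ self.H)
        HH = float(self.H @ self.H)
        self.logdens = uH - 0.5 * c * HH - 0.5 * float(np.sum(beta * beta / lam))
        Hp = smoothed_heaviside_deriv(self.phi, eps)
        self.grad = basis.Psi.T @ ((u - c * self.H) * Hp) - beta / lam
        if metric == "fisher":
            idx = np.flatnonzero(np.abs(self.phi) <= METRIC_CUT_MULT * eps)
            G = np.diag(1.0 / lam)
            if idx.size:
                sub = basis.Psi[idx]
                G += c * (sub * (Hp[idx] ** 2)[:, None]).T @ sub
        else:
            G = np.diag(1.0 / lam)
        try:
            L = np.linalg.cholesky(G)
            self.chol = L
            self.logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            self.ok = np.isfinite(self.logdens) and np.all(np.isfinite(self.grad))
        except np.linalg.LinAlgError:
            self.chol = None
            self.ok = False

    def proposal_mean(self, h):
        v = cho_solve((self.chol, True), self.grad)
        return self.beta + 0.5 * h * v

    def log_q(self, target_beta, h):
        """log density of proposing ``target_beta`` from this point.

        The proposal is N(mean, h G^{-1}), so the exponent carries G/h:
        with G = L L', d'G d = ||L'd||^2.
        """
        d = target_beta - self.proposal_mean(h)
        quad = float(np.sum((self.chol.T @ d) ** 2)) / h
        Ldim = self.beta.shape[0]
        return -0.5 * quad + 0.5 * self.logdet - 0.5 * Ldim * np.log(h) \
            - 0.5 * Ldim * np.log(2.0 * np.pi)


def update_beta(state: ChainState, data: Dataset, basis: BasisExpansion,
                tuning: MMALATuning, rng, eps: float, *,
                u: Optional[np.ndarray] = None,
                phi: Optional[np.ndarray] = None):
    """One MMALA step on beta.

    Proposal: beta' = beta + (h/2) G^{-1} grad + sqrt(h) G^{-1/2} xi with the
    standard Metropolis-Hastings correction for the asymmetric, position-
    dependent proposal.  Returns (new state, accepted flag, geometry at the
    new point).  Non-finite gradients cause a rejection with a warning.
    """
    if u is None:
        u = data.Y.T @ (state.mu / state.sigma2)
    c = float(np.sum(state.mu ** 2 / state.sigma2))
    geom = _BetaGeometry(state.beta, u, c, data, basis, eps, tuning.metric,
                         phi=phi)
    if not geom.ok:
        import warnings

        warnings.warn("non-finite gradient in beta update; step rejected",
                      RuntimeWarning)
        return state, False, geom

    h = tuning.step_size
    L = geom.chol
    xi = rng.standard_normal(state.beta.shape[0])
    noise = solve_triangular(L.T, xi, lower=False)
    beta_prop = geom.proposal_mean(h) + np.sqrt(h) * noise
    prop = _BetaGeometry(beta_prop, u, c, data, basis, eps, tuning.metric)

    accepted = False
    if prop.ok:
        log_alpha = (prop.logdens - geom.logdens
                     + prop.log_q(state.beta, h) - geom.log_q(beta_prop, h))
        if np.log(rng.uniform()) < log_alpha:
            accepted = True
    acc_prob = min(1.0, np.exp(min(0.0, log_alpha))) if prop.ok else 0.0

    if tuning.adapt:
        tuning.iteration += 1
        # Constant-gain stochastic approximation: recovers quickly from an
        # early step-size collapse in either direction; frozen after burn-in.
        tuning.step_size = float(np.exp(
            np.log(tuning.step_size) + ADAPT_GAIN * (acc_prob - TARGET_ACCEPT)))

    if accepted:
        new_state = dataclasses.replace(state, beta=beta_prop)
        return new_state, True, prop
    return state, False, geom


def update_mu(state: ChainState, data: Dataset, basis: BasisExpansion, rng,
              eps: float, *, H=None, Yh=None):
    """Conjugate draw of all mu_i.

    mu_i | rest ~ N(m_i, V_i) with V_i = (H'H/sigma_i^2 + 1/tau_mu^2)^{-1},
    m_i = V_i (H'y_i/sigma_i^2 + s_i'eta/tau_mu^2).
    """
    if H is None:
        H = smoothed_heaviside(basis.Psi @ state.beta, eps)
    if Yh is None:
        Yh = data.Y @ H
    HtH = float(H @ H)
    prior_mean = data.S @ state.eta if data.m else np.zeros(data.n)
    V = 1.0 / (HtH / state.sigma2 + 1.0 / state.tau_mu2)
    m = V * (Yh / state.sigma2 + prior_mean / state.tau_mu2)
    mu = m + np.sqrt(V) * rng.standard_normal(data.n)
    return dataclasses.replace(state, mu=mu)


def mu_conditional_params(state, data, basis, eps):
    """(mean, variance) vectors of the mu full conditional (for testing)."""
    H = smoothed_heaviside(basis.Psi @ state.beta, eps)
    HtH = float(H @ H)
    prior_mean = data.S @ state.eta if data.m else np.zeros(data.n)
    V = 1.0 / (HtH / state.sigma2 + 1.0 / state.tau_mu2)
    m = V * ((data.Y @ H) / state.sigma2 + prior_mean / state.tau_mu2)
    return m, V


def _draw_eta(rng, A, b):
    """eta ~ N(A^{-1} b, A^{-1}) via Cholesky, jittering a singular A."""
    m = A.shape[0]
    jitter = 0.0
    for _ in range(6):
        try:
            cf = cho_factor(A + jitter * np.eye(m), lower=True)
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-10 * np.trace(A) / m)
    else:  # pragma: no cover
        raise np.linalg.LinAlgError("eta precision matrix not factorizable")
    if jitter > 0:
        import warnings

        warnings.warn("jittered singular eta precision matrix", RuntimeWarning)
    mean = cho_solve(cf, b)
    xi = rng.standard_normal(m)
    return mean + solve_triangular(cf[0].T, xi, lower=False), mean, cf


def eta_conditional_params(state, data, hyper, variant="spike_slab", StS=None):
    """(mean, covariance) of the eta full conditional (for testing)."""
    if StS is None:
        StS = data.S.T @ data.S
    if variant == "spike_slab":
        prec_prior = 1.0 / (state.gamma * state.tau2)
    else:
        prec_prior = np.full(data.m, 1.0 / state.tau_eta2)
    A = StS / state.tau_mu2 + np.diag(prec_prior)
    b = data.S.T @ state.mu / state.tau_mu2
    cov = np.linalg.inv(A)
    return cov @ b, cov


def update_eta_ssvs(state: ChainState, data: Dataset, rng,
                    hyper: HyperParams, *, StS=None):
    """Spike-and-slab block: joint eta draw, then gamma, w, tau_k^2.

    Uses the continuous-spike parameterization: eta_k | gamma_k, tau_k^2 ~
    N(0, gamma_k tau_k^2) with gamma_k in {nu0, 1}, so eta is never exactly
    zero and the indicator draw is a two-point conditional with slab odds
    w N(eta_k; 0, tau_k^2) / [(1-w) N(eta_k; 0, nu0 tau_k^2)].
    """
    if data.m == 0:
        raise ValueError("no variants to update")
    if StS is None:
        StS = data.S.T @ data.S
    A = StS / state.tau_mu2 + np.diag(1.0 / (state.gamma * state.tau2))
    b = data.S.T @ state.mu / state.tau_mu2
    eta, _, _ = _draw_eta(rng, A, b)

    e2t = eta ** 2 / state.tau2
    log_slab = np.log(state.w) - 0.5 * np.log(state.tau2) - 0.5 * e2t
    log_spike = (np.log1p(-state.w) - 0.5 * np.log(hyper.nu0 * state.tau2)
                 - 0.5 * e2t / hyper.nu0)
    p_slab = 1.0 / (1.0 + np.exp(np.clip(log_spike - log_slab, -700, 700)))
    gamma = np.where(rng.uniform(size=data.m) < p_slab, 1.0, hyper.nu0)

    k1 = int(np.sum(gamma == 1.0))
    w = rng.beta(1.0 + k1, 1.0 + data.m - k1)
    tau2 = _sample_invgamma(rng, hyper.c1 + 0.5,
                            hyper.c2 + eta ** 2 / (2.0 * gamma))
    return dataclasses.replace(state, eta=eta, gamma=gamma, w=float(w), tau2=tau2)


def update_eta_ssvs_collapsed(state: ChainState, data: Dataset, rng,
                              hyper: HyperParams, *, StS=None):
    """Single-site (gamma_k, eta_k) scan with eta_k integrated out of the
    indicator draw, followed by a joint eta refresh, then w and tau_k^2.

    Conditioning gamma_k on the current eta_k (as ``update_eta_ssvs`` does)
    makes the spike nearly absorbing for a true effect — escaping requires a
    rare tail draw of eta_k — so the chain can take thousands of scans to
    pick up a signal from a cold start.  Drawing gamma_k from the marginal
    evidence ratio instead moves effects between spike and slab freely.  The
    driver uses this kernel during burn-in and the standard blocking for the
    saved draws; both leave the posterior invariant.
    """
    if data.m == 0:
        raise ValueError("no variants to update")
    if StS is None:
        StS = data.S.T @ data.S
    m = data.m
    tau_mu2 = state.tau_mu2
    b = data.S.T @ state.mu / tau_mu2          # S'mu / tau_mu^2
    diagG = np.diag(StS)
    eta = state.eta.copy()
    gamma = state.gamma.copy()
    Geta = StS @ eta
    log_prior_odds = np.log(state.w) - np.log1p(-state.w)
    for k in range(m):
        # d_k = S_k' (mu - S_{-k} eta_{-k}) / tau_mu2; s_k = S_k'S_k / tau_mu2
        d = b[k] - (Geta[k] - diagG[k] * eta[k]) / tau_mu2
        s = diagG[k] / tau_mu2
        evid = []
        for v in (state.tau2[k], hyper.nu0 * state.tau2[k]):
            a = s + 1.0 / v
            evid.append(0.5 * (d * d / a - np.log(v * a)))
        log_odds = log_prior_odds + evid[0] - evid[1]
        if abs(log_odds) < 700:
            slab = np.log(rng.uniform()) < -np.log1p(np.exp(-log_odds))
        else:
            slab = log_odds > 0
        gamma[k] = 1.0 if slab else hyper.nu0
        a = s + 1.0 / (gamma[k] * state.tau2[k])
        new_eta = d / a + rng.standard_normal() / np.sqrt(a)
        Geta += StS[:, k] * (new_eta - eta[k])
        eta[k] = new_eta

    A = StS / tau_mu2 + np.diag(1.0 / (gamma * state.tau2))
    eta, _, _ = _draw_eta(rng, A, b)

    k1 = int(np.sum(gamma == 1.0))
    w = rng.beta(1.0 + k1, 1.0 + m - k1)
    tau2 = _sample_invgamma(rng, hyper.c1 + 0.5,
                            hyper.c2 + eta ** 2 / (2.0 * gamma))
    return dataclasses.replace(state, eta=eta, gamma=gamma, w=float(w), tau2=tau2)


def update_eta_normal(state: ChainState, data: Dataset, rng,
                      hyper: HyperParams, *, StS=None):
    """Normal-prior block: eta | rest ~ N(A^{-1} S'mu/tau_mu^2, A^{-1}) with
    A = S'S/tau_mu^2 + I/tau_eta^2, then tau_eta^2 ~ IG(d1 + m/2, d2 + |eta|^2/2)."""
    if data.m == 0:
        raise ValueError("no variants to update")
    if StS is None:
        StS = data.S.T @ data.S
    A = StS / state.tau_mu2 + np.eye(data.m) / state.tau_eta2
    b = data.S.T @ state.mu / state.tau_mu2
    eta, _, _ = _draw_eta(rng, A, b)
    tau_eta2 = float(_sample_invgamma(
        rng, hyper.d1 + data.m / 2.0, hyper.d2 + float(eta @ eta) / 2.0))
    return dataclasses.replace(state, eta=eta, tau_eta2=tau_eta2)


def update_variances(state: ChainState, data: Dataset, basis: BasisExpansion,
                     rng, hyper: HyperParams, eps: float, *,
                     H=None, Yh=None, yy=None):
    """Conjugate inverse-gamma draws of sigma_i^2 and tau_mu^2."""
    if H is None:
        H = smoothed_heaviside(basis.Psi @ state.beta, eps)
    if Yh is None:
        Yh = data.Y @ H
    if yy is None:
        yy = np.einsum("ij,ij->i", data.Y, data.Y)
    HtH = float(H @ H)
    r2 = np.maximum(yy - 2.0 * state.mu * Yh + state.mu ** 2 * HtH, 0.0)
    sigma2 = _sample_invgamma(rng, hyper.a1 + data.p / 2.0, hyper.a2 + r2 / 2.0)
    prior_mean = data.S @ state.eta if data.m else np.zeros(data.n)
    ssr = float(np.sum((state.mu - prior_mean) ** 2))
    tau_mu2 = float(_sample_invgamma(rng, hyper.b1 + data.n / 2.0,
                                     hyper.b2 + ssr / 2.0))
    return dataclasses.replace(state, sigma2=sigma2, tau_mu2=tau_mu2)


def initialize_state(data: Dataset, basis: BasisExpansion,
                     hyper: HyperParams, rng) -> ChainState:
    """Signal-agnostic starting point.

    beta starts at a small (0.1x) prior draw — beta = 0 is degenerate since it
    puts H = 1/2 everywhere; mu_i starts at the mean of subject i's top-decile
    voxel intensities; variances by method of moments.  The spike-and-slab
    indicators start in the slab: the slab-to-spike direction mixes in a few
    scans (a null effect is shrunk and captured almost immediately) whereas
    escaping the spike requires a rare tail draw of eta_k, so a spike start
    can leave true effects undetected for thousands of iterations.
    """
    L = basis.L
    beta = 0.1 * np.sqrt(basis.eigenvalues) * rng.standard_normal(L)
    q90 = np.quantile(data.Y, 0.9, axis=1, keepdims=True)
    top = np.where(data.Y >= q90, data.Y, np.nan)
    mu = np.nanmean(top, axis=1)
    sigma2 = np.maximum(np.var(data.Y, axis=1), 1e-8)
    tau_mu2 = float(np.var(mu) + 1e-3)
    m = data.m
    return ChainState(
        beta=beta, mu=mu, eta=np.zeros(m),
        gamma=np.ones(m), w=0.5, sigma2=sigma2,
        tau_mu2=tau_mu2, tau2=np.ones(m), tau_eta2=1.0,
    )


def run_chain(data: Dataset, basis: BasisExpansion, config: RunConfig,
              init: Optional[ChainState] = None) -> PosteriorDraws:
    """Run the full systematic-scan Gibbs sampler and collect thinned draws."""
    hyper = config.hyper
    eps = hyper.eps
    rng = np.random.default_rng(config.seed)
    state = init.copy() if init is not None else initialize_state(
        data, basis, hyper, rng)

    n, m, L = data.n, data.m, basis.L
    yy = np.einsum("ij,ij->i", data.Y, data.Y)
    StS = data.S.T @ data.S if m else None
    tuning = MMALATuning(step_size=config.step_size, metric=config.metric,
                         adapt=config.adapt)

    n_save = (config.n_iter - config.n_burnin) // config.thin
    out = PosteriorDraws(
        beta=np.empty((n_save, L)), mu=np.empty((n_save, n)),
        eta=np.empty((n_save, m)), gamma=np.empty((n_save, m)),
        w=np.empty(n_save), sigma2=np.empty((n_save, n)),
        tau_mu2=np.empty(n_save), tau2=np.empty((n_save, m)),
        tau_eta2=np.empty(n_save), accept_rate=0.0,
        step_size=config.step_size, prior_variant=config.prior_variant,
        seed=config.seed, config=_config_dict(config),
    )

    # Smooth-to-sharp continuation on the Heaviside width during the first
    # half of burn-in: with a wide H_eps the likelihood is smooth in phi and
    # the level set migrates freely; eps then decays geometrically to its
    # target, sharpening the boundary before any draw is saved.
    anneal_end = config.n_burnin // 2
    eps0 = max(config.anneal_eps0, eps)

    phi = None
    n_acc_post = 0
    n_post = 0
    save_i = 0
    for t in range(config.n_iter):
        tuning.adapt = config.adapt and t < config.n_burnin
        if t < anneal_end and eps0 > eps:
            eps_t = float(eps * (eps0 / eps) ** (1.0 - t / anneal_end))
        else:
            eps_t = eps
        u = data.Y.T @ (state.mu / state.sigma2)
        state, accepted, geom = update_beta(
            state, data, basis, tuning, rng, eps_t, u=u, phi=phi)
        phi = geom.phi
        if t >= config.n_burnin:
            n_post += 1
            n_acc_post += accepted

        H = geom.H
        Yh = data.Y @ H
        state = update_mu(state, data, basis, rng, eps, H=H, Yh=Yh)
        if m:
            if config.prior_variant == "spike_slab":
                # Collapsed kernel early in burn-in (escapes the absorbing
                # spike from a cold start); the standard blocking takes over
                # well before saving so its transients die out first.
                if t < config.n_burnin // 2:
                    state = update_eta_ssvs_collapsed(state, data, rng, hyper,
                                                      StS=StS)
                else:
                    state = update_eta_ssvs(state, data, rng, hyper, StS=StS)
            else:
                state = update_eta_normal(state, data, rng, hyper, StS=StS)
        state = update_variances(state, data, basis, rng, hyper, eps,
                                 H=H, Yh=Yh, yy=yy)

        if not (np.all(np.isfinite(state.mu)) and np.isfinite(state.tau_mu2)):
            raise RuntimeError(
                f"chain diverged at iteration {t}: non-finite state "
                f"(tau_mu2={state.tau_mu2!r})")

        if t >= config.n_burnin and (t - config.n_burnin) % config.thin == config.thin - 1 \
                and save_i < n_save:
            out.beta[save_i] = state.beta
            out.mu[save_i] = state.mu
            out.eta[save_i] = state.eta
            out.gamma[save_i] = state.gamma
            out.w[save_i] = state.w
            out.sigma2[save_i] = state.sigma2
            out.tau_mu2[save_i] = state.tau_mu2
            out.tau2[save_i] = state.tau2
            out.tau_eta2[save_i] = state.tau_eta2
            save_i += 1

    out.accept_rate = n_acc_post / max(n_post, 1)
    out.step_size = tuning.step_size
    return out


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
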