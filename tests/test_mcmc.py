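import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from bnls import (
    ChainState,
    Dataset,
    Grid,
    HyperParams,
    KernelSpec,
    MMALATuning,
    PosteriorDraws,
    RunConfig,
    build_basis,
    run_chain,
    update_beta,
    update_eta_normal,
    update_eta_ssvs,
    update_mu,
    update_variances,
)
from bnls.forward_model import smoothed_heaviside
from bnls.mcmc import eta_conditional_params, mu_conditional_params


def _state(L, n, m, rng, **kw):
    base = dict(beta=0.2 * rng.standard_normal(L), mu=rng.normal(1, 0.3, n),
                eta=np.zeros(m), gamma=np.ones(m), w=0.5,
                sigma2=rng.uniform(0.5, 1.5, n), tau_mu2=0.8,
                tau2=np.ones(m), tau_eta2=1.0)
    base.update(kw)
    return ChainState(**base)


class TestUpdateMu:
    def test_no_likelihood_information_returns_prior(self):
        rng = np.random.default_rng(0)
        grid = Grid.regular((3, 3))
        basis = build_basis(grid, KernelSpec(), 0.99)
        data = Dataset(Y=rng.normal(0, 1, (2, grid.p)),
                       S=rng.standard_normal((2, 2)), grid=grid)
        # strongly negative field -> H ~ 0 -> posterior = prior N(s_i'eta, tau_mu2)
        beta = -1e7 * basis.Psi.T @ np.ones(grid.p)
        st = _state(basis.L, 2, 2, rng, beta=beta, eta=np.array([0.4, -0.1]))
        m, V = mu_conditional_params(st, data, basis, eps=1e-3)
        assert np.allclose(m, data.S @ st.eta, atol=1e-5)
        assert np.allclose(V, st.tau_mu2, rtol=1e-5)

    def test_flat_prior_limit_is_least_squares(self):
        rng = np.random.default_rng(1)
        grid = Grid.regular((3, 3))
        basis = build_basis(grid, KernelSpec(), 0.99)
        data = Dataset(Y=rng.normal(1, 1, (2, grid.p)), S=np.zeros((2, 0)),
                       grid=grid)
        st = _state(basis.L, 2, 0, rng, tau_mu2=1e12)
        m, _ = mu_conditional_params(st, data, basis, eps=1e-3)
        H = smoothed_heaviside(basis.Psi @ st.beta, 1e-3)
        assert np.allclose(m, data.Y @ H / (H @ H), rtol=1e-6)

    def test_sampling_uses_conditional_params(self):
        rng = np.random.default_rng(2)
        grid = Grid.regular((4, 4))
        basis = build_basis(grid, KernelSpec(), 0.95)
        data = Dataset(Y=rng.normal(1, 1, (3, grid.p)),
                       S=rng.standard_normal((3, 1)), grid=grid)
        st = _state(basis.L, 3, 1, rng, eta=np.array([0.3]))
        m, V = mu_conditional_params(st, data, basis, eps=1e-3)
        draws = np.stack([
            update_mu(st, data, basis, np.random.default_rng(s), 1e-3).mu
            for s in range(4000)])
        assert np.allclose(draws.mean(axis=0), m, atol=4 * np.sqrt(V / 4000).max())
        assert np.allclose(draws.var(axis=0), V, rtol=0.15)


class TestUpdateEta:
    def test_ridge_oracle_with_orthonormal_design(self):
        # S with orthonormal columns, tau_mu2=1: posterior mean of eta_k is
        # (S'mu)_k / (1 + 1/(gamma_k tau_k^2))
        rng = np.random.default_rng(3)
        n, m = 12, 3
        Q, _ = np.linalg.qr(rng.standard_normal((n, m)))
        grid = Grid.regular((2, 2))
        data = Dataset(Y=np.zeros((n, grid.p)), S=Q, grid=grid)
        st = _state(1, n, m, rng, tau_mu2=1.0,
                    gamma=np.array([1.0, 0.05, 1.0]),
                    tau2=np.array([2.0, 1.0, 0.5]))
        mean, cov = eta_conditional_params(st, data, HyperParams())
        expected = (Q.T @ st.mu) / (1.0 + 1.0 / (st.gamma * st.tau2))
        assert np.allclose(mean, expected, rtol=1e-10)
        assert np.allclose(cov, np.diag(1.0 / (1.0 + 1.0 / (st.gamma * st.tau2))),
                           atol=1e-12)

    def test_w_posterior_beta_counting(self):
        # with all indicators in the spike, w | gamma ~ Beta(1, 1+m)
        rng = np.random.default_rng(4)
        n, m = 30, 5
        grid = Grid.regular((2, 2))
        hyper = HyperParams()
        data = Dataset(Y=np.zeros((n, grid.p)),
                       S=0.01 * rng.standard_normal((n, m)), grid=grid)
        st = _state(1, n, m, rng, mu=np.zeros(n),
                    gamma=np.full(m, hyper.nu0))
        ws = []
        for s in range(3000):
            new = update_eta_ssvs(st, data, np.random.default_rng(s), hyper)
            if np.all(new.gamma == hyper.nu0):
                ws.append(new.w)
        ws = np.array(ws)
        assert ws.mean() == pytest.approx(1.0 / (m + 2.0), abs=0.02)

    def test_ssvs_single_variant_matches_marginalization_oracle(self):
        # m=1: stationary P(gamma=1) from the chain vs numeric marginalization
        # over (eta, tau^2, w) of the two-point mixture evidence.
        rng = np.random.default_rng(5)
        n = 25
        S = rng.standard_normal((n, 1))
        S = (S - S.mean()) / S.std()
        eta_true = 0.12
        tau_mu2 = 1.0
        mu = (S[:, 0] * eta_true
              + np.random.default_rng(17).normal(0, np.sqrt(tau_mu2), n))
        grid = Grid.regular((2, 2))
        data = Dataset(Y=np.zeros((n, grid.p)), S=S, grid=grid)
        hyper = HyperParams()

        s_stat = float(S[:, 0] @ S[:, 0]) / tau_mu2
        d_stat = float(S[:, 0] @ mu) / tau_mu2

        def evidence(v):
            a = s_stat + 1.0 / v
            return np.exp(0.5 * (d_stat ** 2 / a - np.log(v * a)))

        def marginal(gam):
            ig = stats.invgamma(hyper.c1, scale=hyper.c2)
            val, _ = quad(lambda t2: ig.pdf(t2) * evidence(gam * t2),
                          0, np.inf, limit=200)
            return val

        # w ~ Uniform(0,1) integrates to prior P(gamma=1) = 1/2
        m1, m0 = marginal(1.0), marginal(hyper.nu0)
        p_slab = m1 / (m1 + m0)

        st = _state(1, n, 1, rng, mu=mu, tau_mu2=tau_mu2)
        rg = np.random.default_rng(6)
        hits = []
        for t in range(12000):
            st = update_eta_ssvs(st, data, rg, hyper)
            if t >= 2000:
                hits.append(st.gamma[0] == 1.0)
        freq = np.mean(hits)
        assert 0.05 < p_slab < 0.95  # informative test point
        assert freq == pytest.approx(p_slab, abs=0.05)

    def test_normal_variant_flat_prior_limit_is_ols(self):
        rng = np.random.default_rng(7)
        n, m = 40, 3
        S = rng.standard_normal((n, m))
        grid = Grid.regular((2, 2))
        data = Dataset(Y=np.zeros((n, grid.p)), S=S, grid=grid)
        st = _state(1, n, m, rng, mu=rng.normal(0, 1, n), tau_eta2=1e12,
                    tau_mu2=1.0)
        mean, _ = eta_conditional_params(st, data, HyperParams(), variant="normal")
        ols = np.linalg.lstsq(S, st.mu, rcond=None)[0]
        assert np.allclose(mean, ols, rtol=1e-6)

    def test_normal_variant_zero_design_returns_prior(self):
        rng = np.random.default_rng(8)
        n, m = 10, 2
        grid = Grid.regular((2, 2))
        data = Dataset(Y=np.zeros((n, grid.p)), S=np.zeros((n, m)), grid=grid)
        st = _state(1, n, m, rng, tau_eta2=2.0)
        mean, cov = eta_conditional_params(st, data, HyperParams(), variant="normal")
        assert np.allclose(mean, 0.0)
        assert np.allclose(cov, 2.0 * np.eye(m))

    def test_no_variants_raises(self):
        rng = np.random.default_rng(9)
        grid = Grid.regular((2, 2))
        data = Dataset(Y=np.zeros((2, grid.p)), S=np.zeros((2, 0)), grid=grid)
        st = _state(1, 2, 0, rng)
        with pytest.raises(ValueError):
            update_eta_ssvs(st, data, rng, HyperParams())


class TestUpdateVariances:
    def test_zero_residuals_posterior_is_prior_rate(self):
        rng = np.random.default_rng(10)
        grid = Grid.regular((4, 4))
        basis = build_basis(grid, KernelSpec(), 0.99)
        hyper = HyperParams(a1=3.0, a2=2.0)
        st = _state(basis.L, 2, 0, rng)
        H = smoothed_heaviside(basis.Psi @ st.beta, hyper.eps)
        data = Dataset(Y=st.mu[:, None] * H[None, :], S=np.zeros((2, 0)),
                       grid=grid)
        draws = np.stack([
            update_variances(st, data, basis, np.random.default_rng(s), hyper,
                             hyper.eps).sigma2
            for s in range(6000)])
        # sigma_i^2 ~ IG(a1 + p/2, a2): mean = a2 / (a1 + p/2 - 1)
        expected = hyper.a2 / (hyper.a1 + grid.p / 2 - 1)
        assert np.allclose(draws.mean(axis=0), expected, rtol=0.05)

    def test_sampled_sigma2_matches_invgamma_distribution(self):
        rng = np.random.default_rng(11)
        grid = Grid.regular((3, 3))
        basis = build_basis(grid, KernelSpec(), 0.99)
        hyper = HyperParams()
        data = Dataset(Y=rng.normal(1, 1, (1, grid.p)), S=np.zeros((1, 0)),
                       grid=grid)
        st = _state(basis.L, 1, 0, rng, mu=np.array([1.0]))
        H = smoothed_heaviside(basis.Psi @ st.beta, hyper.eps)
        r2 = float(np.sum((data.Y[0] - st.mu[0] * H) ** 2))
        draws = np.array([
            update_variances(st, data, basis, np.random.default_rng(s), hyper,
                             hyper.eps).sigma2[0]
            for s in range(3000)])
        ks = stats.kstest(draws, stats.invgamma(
            hyper.a1 + grid.p / 2, scale=hyper.a2 + r2 / 2).cdf)
        assert ks.pvalue > 0.01

    def test_tau_mu2_uses_regression_residual(self):
        rng = np.random.default_rng(12)
        grid = Grid.regular((3, 3))
        basis = build_basis(grid, KernelSpec(), 0.99)
        hyper = HyperParams(b1=2.0, b2=1.0)
        n = 50
        data = Dataset(Y=rng.normal(0, 1, (n, grid.p)),
                       S=rng.standard_normal((n, 2)), grid=grid)
        st = _state(basis.L, n, 2, rng, eta=np.array([1.0, -0.5]))
        ssr = float(np.sum((st.mu - data.S @ st.eta) ** 2))
        draws = np.array([
            update_variances(st, data, basis, np.random.default_rng(s), hyper,
                             hyper.eps).tau_mu2
            for s in range(4000)])
        expected_mean = (hyper.b2 + ssr / 2) / (hyper.b1 + n / 2 - 1)
        assert draws.mean() == pytest.approx(expected_mean, rel=0.05)


class TestUpdateBeta:
    def test_vanishing_step_accepts_and_stays(self):
        rng = np.random.default_rng(13)
        grid = Grid.regular((4, 4))
        basis = build_basis(grid, KernelSpec(), 0.9)
        data = Dataset(Y=rng.normal(0.5, 1, (2, grid.p)), S=np.zeros((2, 0)),
                       grid=grid)
        st = _state(basis.L, 2, 0, rng)
        tuning = MMALATuning(step_size=1e-14, adapt=False)
        n_acc = 0
        for s in range(50):
            new, acc, _ = update_beta(st, data, basis, tuning,
                                      np.random.default_rng(s), eps=1e-2)
            n_acc += acc
            if acc:
                assert np.abs(new.beta - st.beta).max() < 1e-5
        assert n_acc >= 48

    def test_prior_only_stationary_law(self):
        # mu = 0 removes the likelihood: beta full conditional is N(0, Lambda)
        rng = np.random.default_rng(14)
        grid = Grid.regular((5, 5))
        basis = build_basis(grid, KernelSpec(inverse_scale=3.0), 0.9)
        data = Dataset(Y=rng.normal(0, 1, (2, grid.p)), S=np.zeros((2, 0)),
                       grid=grid)
        st = _state(basis.L, 2, 0, rng, mu=np.zeros(2))
        tuning = MMALATuning(step_size=1.0, adapt=True)
        draws = []
        for t in range(12000):
            tuning.adapt = t < 2000
            st, _, _ = update_beta(st, data, basis, tuning, rng, eps=1e-3)
            if t >= 4000:
                draws.append(st.beta.copy())
        draws = np.array(draws)
        lam = basis.eigenvalues
        assert np.abs(draws.mean(axis=0) / np.sqrt(lam)).max() < 0.25
        assert np.allclose(draws.var(axis=0), lam, rtol=0.30)

    def test_single_basis_toy_matches_quadrature(self):
        # L=1, p=4, n=1: the exact conditional density is a 1-D integral
        rng = np.random.default_rng(15)
        grid = Grid.from_points(np.array([[-0.6, 0], [-0.2, 0], [0.2, 0], [0.6, 0]]))
        basis_full = build_basis(grid, KernelSpec(inverse_scale=0.5), 0.999)
        basis = dataclasses.replace(
            basis_full, eigenvalues=basis_full.eigenvalues[:1],
            Psi=np.ascontiguousarray(basis_full.Psi[:, :1]))
        y = np.array([[1.1, 0.9, -0.1, 0.2]])
        data = Dataset(Y=y, S=np.zeros((1, 0)), grid=grid)
        st = _state(1, 1, 0, rng, mu=np.array([1.0]), sigma2=np.array([0.5]))
        eps = 0.05

        def logpost(b):
            H = smoothed_heaviside(basis.Psi[:, 0] * b, eps)
            return (-np.sum((y[0] - H) ** 2) / (2 * 0.5)
                    - b ** 2 / (2 * basis.eigenvalues[0]))

        grid_b = np.linspace(-8, 8, 4001)
        dens = np.exp([logpost(b) for b in grid_b])
        dens /= np.trapezoid(dens, grid_b)
        mean_q = np.trapezoid(grid_b * dens, grid_b)
        var_q = np.trapezoid((grid_b - mean_q) ** 2 * dens, grid_b)

        tuning = MMALATuning(step_size=1.0, adapt=True)
        bs = []
        for t in range(25000):
            tuning.adapt = t < 3000
            st, _, _ = update_beta(st, data, basis, tuning, rng, eps)
            if t >= 5000:
                bs.append(st.beta[0])
        bs = np.array(bs)
        se = bs.std() / np.sqrt(len(bs) / 50)  # crude autocorrelation allowance
        assert bs.mean() == pytest.approx(mean_q, abs=4 * se)
        assert bs.var() == pytest.approx(var_q, rel=0.25)


class TestRunChain:
    @pytest.fixture(scope="class")
    def small_run(self):
        from bnls import SimConfig, simulate_dataset

        cfg = SimConfig(shape_kind="circle", grid_shape=(8, 8), n=4, m=6,
                        n_active=2, snr_beta=4.0, snr_eta=4.0, seed=5)
        data, truth = simulate_dataset(cfg)
        basis = build_basis(data.grid, cfg.kernel, 0.8)
        return data, truth, basis

    def test_seed_determinism(self, small_run):
        data, _, basis = small_run
        rc = RunConfig(n_iter=200, n_burnin=100, thin=2, seed=3,
                       hyper=HyperParams(eps=1e-3))
        d1 = run_chain(data, basis, rc)
        d2 = run_chain(data, basis, rc)
        assert np.array_equal(d1.beta, d2.beta)
        assert np.array_equal(d1.eta, d2.eta)
        assert d1.accept_rate == d2.accept_rate

    def test_saved_count_and_diagnostics(self, small_run):
        data, _, basis = small_run
        rc = RunConfig(n_iter=230, n_burnin=100, thin=3, seed=1,
                       hyper=HyperParams(eps=1e-3))
        d = run_chain(data, basis, rc)
        assert d.n_saved == (230 - 100) // 3
        assert 0.0 <= d.accept_rate <= 1.0
        assert d.beta.shape == (d.n_saved, basis.L)
        assert d.mu.shape == (d.n_saved, data.n)

    def test_normal_variant_runs_and_records(self, small_run):
        data, _, basis = small_run
        rc = RunConfig(n_iter=200, n_burnin=100, seed=2, prior_variant="normal",
                       hyper=HyperParams(eps=1e-3))
        d = run_chain(data, basis, rc)
        assert d.prior_variant == "normal"
        assert np.all(d.tau_eta2 > 0)

    def test_hdf5_round_trip(self, small_run, tmp_path):
        data, _, basis = small_run
        rc = RunConfig(n_iter=120, n_burnin=60, seed=4, hyper=HyperParams(eps=1e-3))
        d = run_chain(data, basis, rc)
        path = tmp_path / "chain.h5"
        d.to_hdf5(path)
        d2 = PosteriorDraws.from_hdf5(path)
        assert np.array_equal(d.beta, d2.beta)
        assert np.array_equal(d.gamma, d2.gamma)
        assert d2.seed == 4 and d2.prior_variant == "spike_slab"

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RunConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            RunConfig(thin=0)
        with pytest.raises(ValueError):
            RunConfig(prior_variant="lasso")
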