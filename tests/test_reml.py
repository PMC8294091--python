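"""REML fitting and BLUP prediction against independent oracles."""

import numpy as np
import pandas as pd
import pytest

import forestblup as fb
from forestblup.reml import MODEL_SPECS, ModelSpec, goodness_of_fit, model_comparison


def restricted_loglik_oracle(y, K, s2u, s2e, intercept=True):
    """Explicit restricted log-likelihood, written independently of the
    fitting code: direct dense formula with slogdet and lstsq."""
    n = len(y)
    V = s2u * K + s2e * np.eye(n)
    Vinv = np.linalg.inv(V)
    sign, logdetV = np.linalg.slogdet(V)
    assert sign > 0
    if intercept:
        X = np.ones((n, 1))
        XtVinvX = X.T @ Vinv @ X
        beta = np.linalg.solve(XtVinvX, X.T @ Vinv @ y)
        r = y - X @ beta
        quad = r @ Vinv @ r
        _, logdetX = np.linalg.slogdet(XtVinvX)
        p = 1
    else:
        quad = y @ Vinv @ y
        logdetX = 0.0
        p = 0
    return -0.5 * ((n - p) * np.log(2 * np.pi) + logdetV + logdetX + quad)


@pytest.fixture(scope="module")
def tiny_kernel():
    rng = np.random.default_rng(77)
    Z = rng.standard_normal((12, 6))
    K = Z @ Z.T / 6 + 0.05 * np.eye(12)
    return K / np.mean(np.diag(K))


class TestFitReml:
    def test_grid_search_oracle_single_kernel(self, tiny_kernel):
        """n=12, one genomic kernel: the AI-REML optimum matches a 200x200
        grid search of the explicit restricted likelihood to within one
        grid cell."""
        rng = np.random.default_rng(5)
        n = 12
        L = np.linalg.cholesky(tiny_kernel)
        y = 3.0 + 1.2 * (L @ rng.standard_normal(n)) + rng.normal(0, 1.0, n)
        kernels = {"G_A": tiny_kernel}
        res = fb.KernelMixedModel(y, kernels, spec="GBLUP-A").fit()
        grid = np.linspace(0.01, 8.0, 200)
        best, best_ll = None, -np.inf
        for su in grid:
            for se in grid:
                ll = restricted_loglik_oracle(y, tiny_kernel, su, se)
                if ll > best_ll:
                    best, best_ll = (su, se), ll
        cell = grid[1] - grid[0]
        assert abs(res.theta[0] - best[0]) <= cell
        assert abs(res.theta[1] - best[1]) <= cell
        assert res.loglik >= best_ll - 1e-6

    def test_loglike_agrees_with_oracle_formula(self, tiny_kernel):
        rng = np.random.default_rng(6)
        y = rng.normal(2.0, 1.0, 12)
        m = fb.KernelMixedModel(y, {"G_A": tiny_kernel}, spec="GBLUP-A")
        for su, se in [(0.5, 1.0), (2.0, 0.3), (0.01, 4.0)]:
            assert m.loglike([su, se]) == pytest.approx(
                restricted_loglik_oracle(y, tiny_kernel, su, se), abs=1e-8
            )

    def test_two_kernel_grid_oracle(self):
        """<=2 kernels: AI-REML matches a coarse 3-d grid refinement of the
        explicit restricted likelihood."""
        rng = np.random.default_rng(8)
        n = 15
        Z1 = rng.standard_normal((n, 8))
        Z2 = rng.standard_normal((n, 8))
        K1 = Z1 @ Z1.T / 8 + 0.05 * np.eye(n)
        K2 = Z2 @ Z2.T / 8 + 0.05 * np.eye(n)
        y = 1.0 + (np.linalg.cholesky(K1) @ rng.standard_normal(n)) \
            + rng.normal(0, 1, n)
        spec = ModelSpec("two", (("a", "G_A"), ("d", "G_D")))
        res = fb.KernelMixedModel(y, {"G_A": K1, "G_D": K2}, spec=spec).fit()

        def ll(t):
            V = t[0] * K1 + t[1] * K2 + t[2] * np.eye(n)
            Vinv = np.linalg.inv(V)
            one = np.ones(n)
            s = one @ Vinv @ one
            P = Vinv - np.outer(Vinv @ one, Vinv @ one) / s
            _, logdetV = np.linalg.slogdet(V)
            return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdetV + np.log(s)
                           + y @ P @ y)

        # the fitted optimum beats every point of a surrounding grid
        grid = np.linspace(0.05, 6.0, 25)
        best = max(
            (ll([a, b, c]) for a in grid for b in grid for c in grid)
        )
        assert res.loglik >= best - 1e-6

    def test_near_identity_kernel_warns(self):
        rng = np.random.default_rng(9)
        y = rng.normal(0, 1, 20)
        with pytest.warns(UserWarning, match="not .*identifiable|identity"):
            fb.KernelMixedModel(y, {"G_A": np.eye(20)}, spec="GBLUP-A")

    def test_boundary_flag_when_no_dominance(self, small_sim, small_kernels):
        """Data simulated with sigma2_d = 0: the dominance component is
        driven to the boundary, reported exactly 0 and flagged."""
        y = small_sim.traits.trait("trait")
        res = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-AD").fit()
        vc = res.varcomp
        if res.boundary_flags["sigma2_d"]:
            assert vc["sigma2_d"] == 0.0
        else:  # sampling noise can keep it slightly positive
            assert vc["sigma2_d"] < 0.3 * vc["sigma2_a"]

    def test_gradient_small_at_optimum(self, small_sim, small_kernels):
        y = small_sim.traits.trait("trait")
        res = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-A").fit()
        free = ~res.boundary
        scale = np.var(res.model.y)
        assert np.all(np.abs(res.gradient[free]) * scale < 1e-2)

    def test_permutation_equivariance(self, small_sim, small_kernels):
        y = small_sim.traits.trait("trait")
        res1 = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-AD").fit()
        rng = np.random.default_rng(4)
        perm = rng.permutation(len(y))
        y2 = y.iloc[perm]
        res2 = fb.KernelMixedModel(y2, small_kernels, spec="GBLUP-AD").fit()
        assert np.allclose(res1.theta, res2.theta, rtol=1e-4, atol=1e-8)
        assert res1.loglik == pytest.approx(res2.loglik, abs=1e-4)
        p1 = res1.predict().sort_index()
        p2 = res2.predict().sort_index()
        assert np.allclose(p1["EBV"], p2["EBV"], rtol=1e-4, atol=1e-6)

    def test_constant_phenotype_rejected(self, small_kernels):
        ids = small_kernels.ids
        y = pd.Series(1.0, index=ids)
        with pytest.raises(ValueError, match="constant"):
            fb.KernelMixedModel(y, small_kernels, spec="GBLUP-A")


class TestPredictBlup:
    def test_gaussian_conditioning_oracle(self):
        """n=8, zero-mean model, one kernel: BLUP and PEV equal the
        conditional mean and variance of the joint normal of (u, y)."""
        rng = np.random.default_rng(11)
        n = 8
        Z = rng.standard_normal((n, 5))
        K = Z @ Z.T / 5 + 0.1 * np.eye(n)
        s2u, s2e = 1.7, 0.6
        y = np.linalg.cholesky(s2u * K + s2e * np.eye(n)) @ \
            rng.standard_normal(n)
        m = fb.KernelMixedModel(y, {"G_A": K}, spec="GBLUP-A",
                                intercept=False)
        res = m.results_at([s2u, s2e])
        pred = res.predict()
        # oracle: u | y ~ N(C V^-1 y, C - C V^-1 C), C = s2u K
        C = s2u * K
        V = C + s2e * np.eye(n)
        Vinv = np.linalg.inv(V)
        mean = C @ Vinv @ y
        cov = C - C @ Vinv @ C
        assert np.allclose(pred["EBV"].to_numpy(), mean, atol=1e-8)
        assert np.allclose(
            pred["SEP_EBV"].to_numpy(), np.sqrt(np.diag(cov)), atol=1e-8
        )

    def test_additive_only_egv_equals_ebv(self, small_sim, small_kernels):
        y = small_sim.traits.trait("trait")
        res = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-A").fit()
        pred = res.predict()
        assert np.array_equal(pred["EBV"], pred["EGV"])
        assert np.array_equal(pred["SEP_EBV"], pred["SEP_EGV"])

    def test_noiseless_limit_interpolates(self):
        rng = np.random.default_rng(13)
        n = 30
        Z = rng.standard_normal((n, 40))
        K = Z @ Z.T / 40
        u = np.linalg.cholesky(K + 1e-10 * np.eye(n)) @ rng.standard_normal(n)
        y = 10.0 + 2.0 * u
        m = fb.KernelMixedModel(y, {"G_A": K}, spec="GBLUP-A")
        res = m.results_at([4.0, 1e-6])
        pred = res.predict()
        assert np.allclose(
            pred["EGV"].to_numpy(), y - res.fe_mean, atol=1e-3
        )

    def test_blup_shrinks_relative_to_phenotype(self, small_sim, small_kernels):
        y = small_sim.traits.trait("trait")
        res = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-A").fit()
        h2 = res.theta[0] / res.sigma2_p
        var_ebv = res.predict()["EBV"].var(ddof=1)
        assert var_ebv <= 1.15 * h2 * y.var(ddof=1)

    def test_seps_positive(self, small_sim, small_kernels):
        y = small_sim.traits.trait("trait")
        res = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-AD").fit()
        pred = res.predict()
        assert (pred["SEP_EBV"] > 0).all() and (pred["SEP_EGV"] > 0).all()


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(3)
        n = 20
        Z = rng.standard_normal((n, 30))
        K = Z @ Z.T / 30
        y = np.linalg.cholesky(K + 1e-8 * np.eye(n)) @ rng.standard_normal(n)
        m = fb.KernelMixedModel(y + 5.0, {"G_A": K + 1e-8 * np.eye(n)},
                                spec="GBLUP-A")
        res = m.results_at([1.0, 1e-8])
        gof = goodness_of_fit(res)
        assert gof.r_additive > 0.999
        assert gof.p_additive < 1e-10

    def test_t_statistic_hand_value(self):
        # r = 0.5, n = 27: t = 0.5*5/sqrt(0.75) = 2.8868
        from forestblup.reml import _corr_t

        rng = np.random.default_rng(15)
        # build vectors with exactly r = 0.5
        x = np.concatenate([np.ones(1), np.zeros(26)])
        x = rng.standard_normal(27)
        y = 0.5 * (x - x.mean()) / x.std() + np.sqrt(0.75) * _orthonormal(x, rng)
        r, t, p = _corr_t(x, y)
        assert r == pytest.approx(0.5, abs=1e-12)
        assert t == pytest.approx(2.8868, abs=1e-4)

    def test_orthogonal_prediction(self):
        from forestblup.reml import _corr_t

        rng = np.random.default_rng(16)
        x = rng.standard_normal(40)
        y = _orthonormal(x, rng)
        r, t, p = _corr_t(x, y)
        assert abs(r) < 1e-12 and t == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-9)


def _orthonormal(x, rng):
    """A standardized vector exactly orthogonal to (centered) x."""
    z = rng.standard_normal(len(x))
    xc = x - x.mean()
    z = z - z.mean()
    z = z - (z @ xc) / (xc @ xc) * xc
    return z / z.std()


class TestModelComparison:
    def test_aic_formula(self):
        assert -2 * (-100.0) + 2 * 2 == 204.0

    def test_parameter_penalty_ordering(self):
        class R:
            def __init__(self, label, ll, k):
                self.spec = MODEL_SPECS["GBLUP-A"]
                self.loglik = ll
                self.n_params = k
                self.aic = -2 * ll + 2 * k
                self.spec = ModelSpec(label, (("a", "G_A"),))

        table = model_comparison([R("big", -50.0, 3), R("small", -50.0, 2)])
        assert table.iloc[0]["model"] == "small"
        assert table.iloc[0]["dAIC"] == 0.0

    def test_nested_ad_never_beats_a_without_dominance(self, small_sim,
                                                       small_kernels):
        """With true sigma2_d = 0, the AD model cannot out-rank the A model
        by more than numerical noise (same max logL, extra parameter)."""
        y = small_sim.traits.trait("trait")
        res_a = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-A").fit()
        res_ad = fb.KernelMixedModel(y, small_kernels, spec="GBLUP-AD").fit()
        assert res_ad.loglik >= res_a.loglik - 1e-4  # nested
        assert res_a.aic <= res_ad.aic + 1e-3
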