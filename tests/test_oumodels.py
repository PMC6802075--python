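"""Likelihood core: closed forms, oracles, profiling, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from ouregimes.oumodels import (FitEngine, ModelSpec, bm_covariance, fit_model,
                                half_life, loglik, ou_covariance,
                                ou_expectation, sic, six_model_specs)
from ouregimes.phylo import LineageHistory, TimeTree, lineage_histories
from ouregimes.traitsim import simulate_traits
from ouregimes.validation import (_random_instance, brute_covariance,
                                  brute_expectation)

LN2 = math.log(2.0)


class TestClosedForms:
    def test_single_segment_expectation(self):
        h = [LineageHistory("x", [(0, 1, "r")], 1.0)]
        assert ou_expectation(h, LN2, {"r": 1.0}, 0.0)[0] == pytest.approx(0.5, abs=1e-10)

    def test_two_segment_expectation(self):
        h = [LineageHistory("x", [(0, 0.5, "a"), (0.5, 1, "b")], 1.0)]
        E = ou_expectation(h, LN2, {"a": 0.0, "b": 1.0}, 0.0)[0]
        assert E == pytest.approx(1 - 2 ** -0.5, abs=1e-10)

    def test_large_alpha_reaches_terminal_optimum(self):
        h = [LineageHistory("x", [(0, 0.5, "a"), (0.5, 1, "b")], 1.0)]
        # alpha * (terminal segment length) = 50, so contamination ~ e^-50
        E = ou_expectation(h, 100.0, {"a": 7.0, "b": 1.0}, -3.0)[0]
        assert abs(E - 1.0) < 1e-20

    def test_cherry_covariance(self):
        tree = TimeTree.from_newick("(A:0.5,B:0.5):0.5;")
        V = ou_covariance(tree, LN2, 2 * LN2)
        assert V[0, 0] == pytest.approx(0.75, abs=1e-10)
        assert V[0, 1] == pytest.approx(0.25, abs=1e-10)

    def test_star_split_at_root_uncorrelated(self):
        tree = TimeTree.from_newick("(A:1,B:1);")
        V = ou_covariance(tree, LN2, 1.0)
        assert V[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_bm_covariance_shared_paths(self, three_tip_tree):
        V = bm_covariance(three_tip_tree, 1.0)
        i, j = (three_tip_tree.tip_names.index(n) for n in ("A", "B"))
        k = three_tip_tree.tip_names.index("C")
        assert V[i, j] == pytest.approx(1.0)
        assert V[i, k] == pytest.approx(0.0)
        assert V[i, i] == pytest.approx(2.0)


class TestOracles:
    def test_covariance_matches_kernel_quadrature(self, rng):
        for _ in range(5):
            tree, painting, alpha, sigma2, *_ = _random_instance(rng)
            V = ou_covariance(tree, alpha, sigma2)
            Vb = brute_covariance(tree, alpha, sigma2)
            np.testing.assert_allclose(V, Vb, atol=1e-10)

    def test_expectation_matches_ode_integration(self, rng):
        for _ in range(5):
            tree, painting, alpha, _, theta, x0, _ = _random_instance(rng)
            hists = lineage_histories(tree, painting)
            E = ou_expectation(hists, alpha, theta, x0)
            Eb = brute_expectation(hists, alpha, theta, x0)
            np.testing.assert_allclose(E, Eb, atol=1e-9)

    def test_loglik_matches_scipy_mvn(self, rng):
        for _ in range(10):
            tree, painting, alpha, sigma2, theta, x0, x = _random_instance(rng)
            hists = lineage_histories(tree, painting)
            E = ou_expectation(hists, alpha, theta, x0)
            V = ou_covariance(tree, alpha, sigma2)
            ref = multivariate_normal.logpdf(x, mean=E, cov=V)
            assert loglik(x, E, V) == pytest.approx(ref, abs=1e-10)

    def test_bm_is_small_alpha_limit(self, rng):
        tree, painting, _, sigma2, _, x0, x = _random_instance(rng)
        hists = lineage_histories(tree, painting)
        theta = {r: x0 for r in painting.regimes}
        lnl_ou = loglik(x, ou_expectation(hists, 1e-9, theta, x0),
                        ou_covariance(tree, 1e-9, sigma2))
        lnl_bm = loglik(x, np.full(tree.n_tips, x0), bm_covariance(tree, sigma2))
        assert abs(lnl_ou - lnl_bm) < 1e-4

    def test_ou_covariance_limit_is_bm(self, rng):
        tree, *_ = _random_instance(rng)
        V_ou = ou_covariance(tree, 1e-9, 1.3)
        V_bm = bm_covariance(tree, 1.3)
        np.testing.assert_allclose(V_ou, V_bm, rtol=1e-4)


class TestLoglik:
    def test_unit_gaussian_constant(self):
        val = loglik(np.array([0.0]), np.array([0.0]), np.array([[1.0]]))
        assert val == pytest.approx(-0.5 * math.log(2 * math.pi), abs=1e-10)

    def test_residual_scaling_quadratic(self, rng):
        tree, painting, alpha, sigma2, theta, x0, x = _random_instance(rng)
        V = ou_covariance(tree, alpha, sigma2)
        E = np.zeros(tree.n_tips)
        base = loglik(np.zeros_like(x), E, V)
        l1 = loglik(x, E, V)
        l3 = loglik(3 * x, E, V)
        assert (l3 - base) == pytest.approx(9 * (l1 - base), rel=1e-9)

    def test_non_pd_covariance_names_eigenvalue(self):
        V = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            loglik(np.zeros(2), np.zeros(2), V)


class TestSicHalfLife:
    def test_sic_arithmetic(self):
        assert sic(10.0, 3, 125) == pytest.approx(-20 + 3 * math.log(125), abs=1e-9)

    def test_extra_parameter_costs_ln_n(self):
        assert sic(5.0, 4, 125) - sic(5.0, 3, 125) == pytest.approx(math.log(125))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sic(1.0, 0, 100)
        with pytest.raises(ValueError):
            sic(1.0, 2, 1)

    @pytest.mark.parametrize("alpha,expected", [(LN2, 1.0), (LN2 / 9.5, 9.5)])
    def test_half_life_values(self, alpha, expected):
        assert half_life(alpha) == pytest.approx(expected)

    def test_half_life_monotone_and_positive_only(self):
        assert half_life(1.0) > half_life(2.0)
        with pytest.raises(ValueError):
            half_life(0.0)


class TestSpecs:
    def test_parameter_counts(self):
        specs = six_model_specs()
        assert specs["BM1"].p == 2
        assert specs["OU1"].p == 3
        assert specs["OU2_foss"].p == 4
        assert specs["OU3"].p == 5
        free = six_model_specs(root_policy="free-x0")
        assert free["OU1"].p == 4

    def test_regime_maps_encode_hypotheses(self):
        specs = six_model_specs("arb", "Ma", "Xe")
        assert specs["OU2_foss"].regime_map == {"arb": "arb", "Ma": "foss",
                                                "Xe": "foss"}
        assert specs["OU2_arb&Ma"].regime_map["Ma"] == "arb"
        assert specs["OU2_arb&Xe"].regime_map["Xe"] == "arb"
        assert len(set(specs["OU3"].regime_map.values())) == 3

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec("bad", "XX")
        with pytest.raises(ValueError):
            ModelSpec("bad", "OU")


class TestFitting:
    def test_bm_closed_form_on_cherry(self):
        tree = TimeTree.from_newick("(A:1,B:1);")
        fit = fit_model(tree, None, np.array([1.0, 3.0]), ModelSpec("BM1", "BM"))
        assert fit.x0 == pytest.approx(2.0, abs=1e-9)
        assert fit.sigma2 == pytest.approx(1.0, abs=1e-9)  # ML, divide-by-n

    def test_profiled_theta_equals_direct_maximization(self, small_frame):
        tree, painting, specs = small_frame
        spec = specs["OU2_foss"]
        engine = FitEngine(tree, painting, spec)
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.3, tree.n_tips)
        fit = engine.fit(x)
        hists = lineage_histories(tree, painting)
        t_map = dict(spec.regime_map)

        def neg(theta_vec):
            theta = dict(zip(spec.optima, theta_vec))
            by_regime = {r: theta[t_map[r]] for r in t_map}
            E = ou_expectation(hists, fit.alpha, by_regime, theta[spec.optima[0]])
            V = ou_covariance(tree, fit.alpha, fit.sigma2)
            return -loglik(x, E, V)

        start = np.array([fit.theta[o] + 0.3 for o in spec.optima])
        res = minimize(neg, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        np.testing.assert_allclose(
            res.x, [fit.theta[o] for o in spec.optima], atol=1e-6)

    def test_fit_never_below_truth(self, small_frame):
        tree, painting, specs = small_frame
        from ouregimes.synthetic_data import TraitConfig
        truth = TraitConfig("t").params(specs)
        engine = FitEngine(tree, painting, specs["OU2_foss"])
        E, V = engine.moments(truth)
        batch = simulate_traits(tree, painting, truth, 10, seed=3)
        for d in range(10):
            fit = engine.fit(batch.values[d])
            assert fit.lnl >= loglik(batch.values[d], E, V) - 1e-6

    def test_batch_fit_agrees_with_scalar_fit(self, small_frame):
        tree, painting, specs = small_frame
        from ouregimes.synthetic_data import TraitConfig
        truth = TraitConfig("t").params(specs)
        engine = FitEngine(tree, painting, specs["OU2_foss"])
        batch = simulate_traits(tree, painting, truth, 30, seed=8)
        bf = engine.fit_batch(batch.values)
        for d in range(30):
            exact = engine.fit(batch.values[d])
            assert bf.lnl[d] <= exact.lnl + 1e-9
            assert bf.lnl[d] == pytest.approx(exact.lnl, abs=5e-3)

    def test_covariance_positive_definite_across_alpha_range(self, rng):
        for _ in range(3):
            from ouregimes.synthetic_data import generate_tree
            tree, _ = generate_tree(n_bg=60, n_clade_a=30, n_clade_b=10,
                                    depth=70.0, seed=int(rng.integers(2**31)))
            for alpha in (1e-6, 1e-2, 1.0, 100.0):
                for sigma2 in (1e-6, 1.0, 10.0):
                    np.linalg.cholesky(ou_covariance(tree, alpha, sigma2))

    def test_trait_vector_shape_checked(self, small_frame):
        tree, painting, specs = small_frame
        with pytest.raises(ValueError, match="shape"):
            FitEngine(tree, painting, specs["OU1"]).fit(np.zeros(3))


class TestScalarProperties:
    @given(a1=st.floats(1e-6, 1e3), a2=st.floats(1e-6, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_half_life_strictly_decreasing_in_alpha(self, a1, a2):
        if a1 == a2:
            assert half_life(a1) == half_life(a2)
        else:
            lo, hi = sorted((a1, a2))
            assert half_life(lo) > half_life(hi)

    @given(lnl=st.floats(-1e6, 1e6), p=st.integers(1, 20),
           n=st.integers(2, 10000))
    @settings(max_examples=100, deadline=None)
    def test_sic_penalty_monotone_in_p(self, lnl, p, n):
        assert sic(lnl, p + 1, n) > sic(lnl, p, n)
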