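"""GPCM probabilities, estimation, scoring and information."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import otashort as ot
from otashort.gpcm import GPCMItem, GPCMModel, gpcm_standard_errors
from otashort.gpcm import test_integrated_information as integrated_total

from conftest import random_item


def brute_force_probabilities(a, b, theta):
    """Long-form evaluation of the adjacent-category logistic model."""
    m = len(b) + 1
    weights = []
    for c in range(m):
        s = 0.0
        for v in range(1, c + 1):
            s += a * (theta - b[v - 1])
        weights.append(np.exp(s))
    total = sum(weights)
    return np.array([w / total for w in weights])


# ---------------------------------------------------------------------------
# category probabilities


class TestCategoryProbabilities:
    def test_zero_discrimination_is_uniform(self):
        item = GPCMItem(0.0, [-1.0, -0.5, 0.0, 0.5, 1.0])
        p = ot.category_probabilities(item, 1.7)
        assert np.allclose(p, 1 / 6)

    def test_binary_item_at_threshold_is_half(self):
        for a in (0.3, 1.0, 2.5):
            p = ot.category_probabilities(GPCMItem(a, [0.4]), 0.4)
            assert np.allclose(p, [0.5, 0.5])

    def test_matches_brute_force_long_form(self):
        item = GPCMItem(1.2, [-1.0, 0.0, 1.0])
        p = ot.category_probabilities(item, 0.3)
        assert np.allclose(p, brute_force_probabilities(1.2, [-1, 0, 1], 0.3), atol=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        a=st.floats(0.0, 3.0),
        theta=st.floats(-5.0, 5.0),
        m=st.integers(2, 7),
        seed=st.integers(0, 10_000),
    )
    def test_probabilities_sum_to_one(self, a, theta, m, seed):
        b = np.sort(np.random.default_rng(seed).normal(0, 1.5, m - 1))
        p = ot.category_probabilities(GPCMItem(a, b), theta)
        assert p.shape == (m,)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# marginal likelihood


class TestMarginalLogLikelihood:
    def test_uniform_model_single_binary_item(self):
        model = GPCMModel(items=[GPCMItem(0.0, [0.0])])
        data = pd.DataFrame({"item01": [1.0]})
        assert np.isclose(ot.marginal_log_likelihood(model, data), np.log(0.5))

    def test_is_negative_for_nondegenerate_data(self, rng):
        model = GPCMModel(items=[random_item(rng, m=4) for _ in range(3)])
        data = pd.DataFrame(rng.integers(1, 5, size=(10, 3)).astype(float))
        assert ot.marginal_log_likelihood(model, data) < 0

    def test_matches_dense_quadrature_oracle(self, rng):
        """5 persons x 3 items against a 10001-point rectangular integral."""
        items = [random_item(rng, m=4) for _ in range(3)]
        model = GPCMModel(items=items)
        X = rng.integers(1, 5, size=(5, 3)).astype(float)

        grid = np.linspace(-8, 8, 10_001)
        dx = grid[1] - grid[0]
        ll_oracle = 0.0
        for i in range(5):
            L = np.ones_like(grid)
            for j, it in enumerate(items):
                probs = np.array(
                    [brute_force_probabilities(it.a, it.b, t)[int(X[i, j]) - 1] for t in grid]
                )
                L *= probs
            ll_oracle += np.log(np.sum(L * norm.pdf(grid)) * dx)
        mine = ot.marginal_log_likelihood(model, pd.DataFrame(X))
        assert abs(mine - ll_oracle) < 1e-6

    def test_all_missing_person_excluded_with_warning(self, rng):
        model = GPCMModel(items=[random_item(rng, m=4)])
        data = pd.DataFrame({"item01": [2.0, np.nan]})
        with pytest.warns(UserWarning, match="all responses missing"):
            ll = ot.marginal_log_likelihood(model, data)
        assert np.isfinite(ll)


# ---------------------------------------------------------------------------
# estimation


class TestFitGPCM:
    def test_em_loglik_never_decreases_and_converges(self):
        cfg = ot.SyntheticConfig(
            n_persons=300, n_items=5, n_categories=4, seed=11,
            covariate_correlations=(),
        )
        data = ot.simulate_responses(ot.generate_true_model(cfg), cfg)
        model = ot.fit_gpcm(data)
        hist = np.asarray(model.fit_info["loglik_history"])
        assert np.all(np.diff(hist) >= -1e-7)
        assert model.fit_info["converged"]

    def test_duplicating_every_person_leaves_estimates_unchanged(self):
        cfg = ot.SyntheticConfig(
            n_persons=150, n_items=4, n_categories=3, seed=3,
            covariate_correlations=(),
        )
        data = ot.simulate_responses(ot.generate_true_model(cfg), cfg)
        doubled = pd.concat([data.responses, data.responses], ignore_index=True)
        m1 = ot.fit_gpcm(data, tol=1e-6)
        m2 = ot.fit_gpcm(pd.DataFrame(doubled), tol=1e-6)
        assert np.allclose(m1.discriminations(), m2.discriminations(), atol=1e-4)
        for i1, i2 in zip(m1.items, m2.items):
            assert np.allclose(i1.b, i2.b, atol=1e-4)

    def test_single_category_item_rejected(self):
        data = pd.DataFrame({"item01": [2.0] * 40, "item02": [1.0, 2.0] * 20})
        with pytest.raises(ValueError, match="fewer than 2 observed categories"):
            ot.fit_gpcm(data, n_categories=3)

    def test_recovery_rmse_decreases_with_sample_size(self):
        """RMSE of the discrimination estimates falls monotonically over
        n in {250, 500, 1000, 4000}, averaged over 10 replicates."""
        sizes = [250, 500, 1000, 4000]
        rmse = []
        for n in sizes:
            errs = []
            for rep in range(10):
                cfg = ot.SyntheticConfig(
                    n_persons=n, n_items=8, n_categories=4,
                    discrimination_range=(0.4, 1.6), seed=7000 + rep,
                    covariate_correlations=(),
                )
                true = ot.generate_true_model(cfg)
                est = ot.fit_gpcm(ot.simulate_responses(true, cfg))
                errs.append(
                    np.mean((true.discriminations() - est.discriminations()) ** 2)
                )
            rmse.append(np.sqrt(np.mean(errs)))
        assert all(r2 < r1 for r1, r2 in zip(rmse, rmse[1:]))

    def test_parametric_bootstrap_consistency(self):
        """Refit on data simulated from the fitted model lands within 2 SE
        of the fitted values for at least 90% of parameters."""
        cfg = ot.SyntheticConfig(
            n_persons=1000, n_items=6, n_categories=4,
            discrimination_range=(0.5, 1.5), seed=21, covariate_correlations=(),
        )
        fitted = ot.fit_gpcm(ot.simulate_responses(ot.generate_true_model(cfg), cfg))
        boot_cfg = ot.SyntheticConfig(
            n_persons=2000, n_items=6, n_categories=4,
            discriminations=fitted.discriminations(), seed=22,
            covariate_correlations=(),
        )
        boot_model = fitted.copy()
        boot_data = ot.simulate_responses(boot_model, boot_cfg, n_persons=2000)
        refit = ot.fit_gpcm(boot_data)
        se, _ = gpcm_standard_errors(refit, boot_data)
        est = np.concatenate([np.concatenate([[it.a], it.b]) for it in refit.items])
        truth = np.concatenate([np.concatenate([[it.a], it.b]) for it in fitted.items])
        within = np.abs(est - truth) <= 2 * se
        assert within.mean() >= 0.9


# ---------------------------------------------------------------------------
# EAP scoring


class TestEAPScores:
    def test_flat_likelihood_returns_prior_mean(self):
        model = GPCMModel(items=[GPCMItem(0.0, [-1, 0, 1]) for _ in range(3)])
        data = pd.DataFrame(np.tile([1.0, 3.0, 4.0], (4, 1)))
        assert np.allclose(ot.eap_scores(model, data), 0.0, atol=1e-10)

    def test_monotone_in_each_response(self, rng):
        """Raising one response (others fixed) never lowers the EAP;
        checked exhaustively over all 27 patterns of a 3-item, 3-category
        test."""
        model = GPCMModel(items=[random_item(rng, m=3, a_range=(0.3, 1.5)) for _ in range(3)])
        patterns = np.array(
            [[i, j, k] for i in range(1, 4) for j in range(1, 4) for k in range(1, 4)],
            dtype=float,
        )
        scores = ot.eap_scores(model, pd.DataFrame(patterns))
        lookup = {tuple(p): s for p, s in zip(map(tuple, patterns), scores)}
        for p in map(tuple, patterns):
            for j in range(3):
                if p[j] < 3:
                    q = list(p)
                    q[j] += 1
                    assert lookup[tuple(q)] >= lookup[p] - 1e-12

    def test_symmetric_binary_item_gives_opposite_scores(self):
        model = GPCMModel(items=[GPCMItem(1.0, [0.0])])
        scores = ot.eap_scores(model, pd.DataFrame({"item01": [1.0, 2.0]}))
        assert np.isclose(scores[0], -scores[1], atol=1e-10)
        assert scores[1] > 0


# ---------------------------------------------------------------------------
# information


def finite_difference_information(item, theta, h=1e-4):
    """Oracle: minus the expected second derivative of log P(C | theta)."""
    p0 = ot.category_probabilities(item, theta)
    lp_plus = np.log(ot.category_probabilities(item, theta + h))
    lp_minus = np.log(ot.category_probabilities(item, theta - h))
    d2 = (lp_plus - 2 * np.log(p0) + lp_minus) / h**2
    return float(-(p0 * d2).sum())


class TestInformation:
    def test_zero_discrimination_no_information(self):
        item = GPCMItem(0.0, [-1, 0, 1])
        assert ot.item_information(item, 0.0) == 0.0
        assert ot.integrated_information(item, (-3, 3)) == 0.0

    def test_binary_item_at_threshold(self):
        assert np.isclose(ot.item_information(GPCMItem(1.0, [0.3]), 0.3), 0.25)

    def test_matches_fisher_information_oracle(self, rng):
        for _ in range(10):
            item = random_item(rng)
            theta = float(rng.uniform(-2.5, 2.5))
            assert abs(
                ot.item_information(item, theta)
                - finite_difference_information(item, theta)
            ) < 1e-4

    def test_integrated_matches_adaptive_quadrature(self, rng):
        item = GPCMItem(1.2, [-1.0, 0.0, 1.0])
        oracle, _ = quad(lambda t: ot.item_information(item, t), -3, 3, epsabs=1e-10)
        assert abs(ot.integrated_information(item, (-3, 3)) - oracle) < 1e-6

    def test_narrow_range_is_midpoint_limit(self):
        item = GPCMItem(0.9, [-0.5, 0.5])
        eps = 1e-4
        approx = 2 * eps * ot.item_information(item, 0.0)
        assert np.isclose(ot.integrated_information(item, (-eps, eps)), approx, rtol=1e-6)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            ot.integrated_information(GPCMItem(1.0, [0.0]), (1.0, -1.0))


class TestTestInformation:
    def test_total_is_exact_sum_of_items(self, rng):
        model = GPCMModel(items=[random_item(rng) for _ in range(6)])
        prof = ot.test_information(model)
        assert np.array_equal(prof.total, prof.per_item.sum(axis=0))
        assert np.all(prof.per_item >= 0)

    def test_disjoint_subsets_add_to_union(self, rng):
        model = GPCMModel(items=[random_item(rng) for _ in range(6)])
        grid = np.linspace(-3, 3, 31)
        t1 = ot.test_information(model, [0, 2], grid).total
        t2 = ot.test_information(model, [1, 3, 5], grid).total
        tu = ot.test_information(model, [0, 1, 2, 3, 5], grid).total
        assert np.allclose(t1 + t2, tu, atol=1e-12)

    def test_empty_subset_gives_zero_profile(self, rng):
        model = GPCMModel(items=[random_item(rng)])
        prof = ot.test_information(model, subset=[])
        assert np.all(prof.total == 0)

    def test_integrated_total_additivity(self, rng):
        model = GPCMModel(items=[random_item(rng) for _ in range(4)])
        total = integrated_total(model)
        parts = sum(ot.integrated_information(it) for it in model.items)
        assert np.isclose(total, parts, rtol=1e-12)
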