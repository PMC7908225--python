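"""Polychoric correlations, adequacy statistics, minres EFA and the
unidimensionality gate."""

import numpy as np
import pytest
from scipy.stats import chi2, multivariate_normal

import otashort as ot
from otashort.dimensionality import (
    EFAResult,
    _minres_objective,
    bivariate_normal_cdf,
    polychoric_pair,
)


class TestBivariateNormalCDF:
    def test_matches_scipy_multivariate_normal(self, rng):
        """Dual-route check of the Owen's-T evaluation."""
        for _ in range(100):
            h, k = rng.normal(0, 1.5, 2)
            rho = float(rng.uniform(-0.97, 0.97))
            ref = multivariate_normal.cdf(
                [h, k], mean=[0, 0], cov=[[1, rho], [rho, 1]]
            )
            assert abs(float(bivariate_normal_cdf(h, k, rho)) - ref) < 1e-12

    def test_degenerate_correlations(self):
        assert np.isclose(bivariate_normal_cdf(0.5, 1.0, 1.0), 0.6914624612740131)
        assert np.isclose(bivariate_normal_cdf(0.0, 0.0, -1.0), 0.0)


class TestPolychoric:
    def test_recovers_generating_correlation(self, rng):
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=100_000)
        cuts = [-1.2, -0.4, 0.3, 1.0]
        x = np.digitize(z[:, 0], cuts) + 1.0
        y = np.digitize(z[:, 1], cuts) + 1.0
        assert abs(polychoric_pair(x, y) - 0.5) < 0.02

    def test_independent_items_near_zero(self, rng):
        x = rng.integers(1, 7, 100_000).astype(float)
        y = rng.integers(1, 7, 100_000).astype(float)
        assert abs(polychoric_pair(x, y)) < 0.02

    def test_duplicated_column_near_one(self, rng):
        x = rng.integers(1, 7, 2000).astype(float)
        assert polychoric_pair(x, x) >= 0.999

    def test_degenerate_pair_raises_with_names(self, rng):
        import pandas as pd

        df = pd.DataFrame(
            {"item01": rng.integers(1, 4, 50).astype(float), "item02": np.ones(50)}
        )
        with pytest.raises(ValueError, match="item02"):
            ot.polychoric_matrix(df)

    def test_matrix_symmetric_unit_diagonal(self):
        cfg = ot.SyntheticConfig(
            n_persons=250, n_items=5, seed=2, covariate_correlations=()
        )
        data = ot.simulate_responses(ot.generate_true_model(cfg), cfg)
        R = ot.polychoric_matrix(data)
        assert np.allclose(R, R.T, atol=1e-10)
        assert np.array_equal(np.diag(R), np.ones(5))


class TestKMO:
    def test_two_by_two_is_half_for_any_r(self):
        for r in (0.1, 0.5, -0.7):
            R = np.array([[1.0, r], [r, 1.0]])
            assert np.isclose(ot.kmo_statistic(R), 0.5)

    def test_strong_one_factor_matrix_exceeds_09(self):
        lam = np.full(10, 0.8)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        assert ot.kmo_statistic(R) > 0.9

    def test_near_identity_is_at_most_about_half(self, rng):
        noise = rng.normal(0, 0.01, (6, 6))
        R = np.eye(6) + (noise + noise.T) / 2
        np.fill_diagonal(R, 1.0)
        assert ot.kmo_statistic(R) <= 0.6


class TestBartlett:
    def test_identity_matrix_gives_zero_statistic(self):
        stat, df, p = ot.bartlett_sphericity(np.eye(5), 100)
        assert np.isclose(stat, 0.0) and np.isclose(p, 1.0)

    def test_df_for_21_items(self):
        R = 0.3 * np.ones((21, 21))
        np.fill_diagonal(R, 1.0)
        _, df, _ = ot.bartlett_sphericity(R, 569)
        assert df == 210

    def test_matches_textbook_formula(self, rng):
        lam = rng.uniform(0.3, 0.7, 6)
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        n, p = 200, 6
        stat, df, pv = ot.bartlett_sphericity(R, n)
        expected = -(n - 1 - (2 * p + 5) / 6) * np.log(np.linalg.det(R))
        assert np.isclose(stat, expected)
        assert np.isclose(pv, chi2.sf(expected, p * (p - 1) / 2))


class TestMinresEFA:
    def test_recovers_noiseless_one_factor_structure(self):
        lam = np.array([0.7, 0.55, 0.8, 0.6, 0.75, 0.5])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        res = ot.minres_efa(R, 1)
        assert np.allclose(np.abs(res.loadings[:, 0]), lam, atol=1e-5)
        assert res.objective < 1e-9

    def test_sign_convention_loading_sum_nonnegative(self):
        lam = -np.array([0.7, 0.55, 0.8, 0.6])
        R = np.outer(lam, lam)
        np.fill_diagonal(R, 1.0)
        res = ot.minres_efa(R, 1)
        assert res.loadings[:, 0].sum() >= 0

    def test_two_block_structure_fails_the_gate(self):
        """Two equally strong orthogonal blocks: eigenvalue ratio < 3."""
        lam = 0.7
        block = lam * lam * np.ones((4, 4))
        R = np.block([[block, np.zeros((4, 4))], [np.zeros((4, 4)), block]])
        np.fill_diagonal(R, 1.0)
        res = ot.minres_efa(R, 1)
        decision = ot.unidimensionality_check(res)
        assert decision.eigenvalue_ratio < 3
        assert not decision.passed

    def test_local_optimality_beats_random_restarts(self, rng):
        cfg = ot.SyntheticConfig(
            n_persons=300, n_items=6, seed=14, covariate_correlations=()
        )
        data = ot.simulate_responses(ot.generate_true_model(cfg), cfg)
        R = ot.polychoric_matrix(data)
        res = ot.minres_efa(R, 1)
        for _ in range(20):
            psi = rng.uniform(0.05, 0.95, 6)
            restart = ot.minres_efa(R, 1, psi0=psi)
            assert res.objective <= restart.objective + 1e-6

    def test_ledermann_bound_enforced(self):
        R = np.eye(4)
        with pytest.raises(ValueError):
            ot.minres_efa(R, 3)


class TestUnidimensionalityCheck:
    def _result(self, eigenvalues, var1, loadings=None):
        p = 5 if loadings is None else len(loadings)
        lam = np.full((p, 1), 0.5) if loadings is None else np.asarray(loadings).reshape(-1, 1)
        return EFAResult(
            polychoric=np.eye(p),
            loadings=lam,
            eigenvalues=np.asarray(eigenvalues, dtype=float),
            variance_explained=np.array([var1]),
            communalities=lam[:, 0] ** 2,
            flagged_items=tuple(int(i) for i in np.where(lam[:, 0] < 0)[0]),
        )

    def test_reference_scale_configuration_passes(self):
        """Ratio 5.1 / 1.3 with 24.1% first-factor variance passes."""
        d = ot.unidimensionality_check(self._result([5.1, 1.3], 0.241))
        assert d.passed and d.ratio_ok and d.variance_ok

    def test_small_ratio_fails(self):
        d = ot.unidimensionality_check(self._result([2.0, 1.0], 0.30))
        assert not d.passed and not d.ratio_ok

    def test_all_positive_loadings_empty_removal_list(self):
        d = ot.unidimensionality_check(self._result([5.0, 1.0], 0.30))
        assert d.remove_items == ()

    def test_negative_loading_listed_for_removal(self):
        d = ot.unidimensionality_check(
            self._result([5.0, 1.0], 0.30, loadings=[0.6, 0.5, -0.4, 0.7])
        )
        assert d.remove_items == (2,)

    def test_decision_is_deterministic(self):
        res = self._result([4.0, 1.2], 0.25)
        d1 = ot.unidimensionality_check(res)
        d2 = ot.unidimensionality_check(res)
        assert d1 == d2
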