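"""Covariance, distance regressions, null models, exact tests and gradients."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import tauspread as ts
from tauspread import association
from tauspread.errors import (CollinearityError, InsufficientDataError,
                              RewireFailureError)


class TestResidualize:
    def test_intercept_only_centres_columns(self):
        values = pd.DataFrame({"r0": [1.0, 2.0, 3.0], "r1": [2.0, 2.0, 5.0]})
        resid = ts.residualize(values, None)
        np.testing.assert_allclose(resid.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(resid["r0"], [-1, 0, 1])

    def test_exact_linear_dependence_gives_zero_residuals(self):
        ages = pd.DataFrame({"age": [60.0, 65.0, 70.0, 75.0]})
        values = pd.DataFrame({"r0": 0.01 * ages["age"] + 1.0})
        resid = ts.residualize(values, ages)
        np.testing.assert_allclose(resid, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(5, 3)))
        cov = pd.DataFrame({"age": [60, 62, 71, 68, 75.0],
                            "sex": ["f", "m", "f", "f", "m"]})
        resid = ts.residualize(values, cov)
        x = np.column_stack([np.ones(5), cov["age"],
                             (cov["sex"] == "m").astype(float)])
        beta = np.linalg.solve(x.T @ x, x.T @ values.to_numpy())
        expected = values.to_numpy() - x @ beta
        np.testing.assert_allclose(resid.to_numpy(), expected, atol=1e-10)
        # residuals orthogonal to every design column
        np.testing.assert_allclose(x.T @ resid.to_numpy(), 0.0, atol=1e-9)

    def test_rank_deficient_design_names_columns(self):
        cov = pd.DataFrame({"age": [60.0, 65.0, 70.0],
                            "age_copy": [60.0, 65.0, 70.0]})
        values = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(CollinearityError) as err:
            ts.residualize(values, cov)
        assert "age_copy" in err.value.columns


class TestTauCovariance:
    def test_identical_profiles_clip_to_max_z(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=10)
        values = pd.DataFrame({"r0": base, "r1": base, "r2": rng.normal(size=10)})
        cov = ts.tau_covariance(values)
        assert cov.matrix[0, 1] == pytest.approx(np.arctanh(0.999999))

    def test_hand_computed_toy_matrix(self):
        values = pd.DataFrame({"r0": [1.0, 2.0, 3.0, 4.0],
                               "r1": [1.0, 3.0, 2.0, 4.0],
                               "r2": [4.0, 3.0, 2.0, 1.0]})
        cov = ts.tau_covariance(values)
        r01 = np.corrcoef(values["r0"], values["r1"])[0, 1]
        assert cov.matrix[0, 1] == pytest.approx(np.arctanh(r01))
        assert cov.matrix[0, 2] == pytest.approx(np.arctanh(-0.999999))
        assert np.isnan(cov.matrix[0, 0])

    def test_independent_rois_have_small_partial_correlation(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(size=(1000, 4)))
        cov = ts.tau_covariance(values)
        iu = np.triu_indices(4, k=1)
        assert np.all(np.abs(np.tanh(cov.matrix[iu])) < 0.1)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(8, 30), st.integers(3, 10))
    def test_partial_correlation_matches_regress_then_correlate(self, seed, n, k):
        """Adjusted covariance equals the brute-force two-stage oracle."""
        rng = np.random.default_rng(seed)
        values = pd.DataFrame(rng.normal(size=(n, k)))
        covs = pd.DataFrame({"age": rng.uniform(55, 85, n),
                             "sex": rng.choice(["f", "m"], n)})
        cov = ts.tau_covariance(values, covs)
        x = np.column_stack([np.ones(n), covs["age"],
                             (covs["sex"] == "m").astype(float)])
        resid = values.to_numpy() - x @ np.linalg.lstsq(x, values.to_numpy(),
                                                        rcond=None)[0]
        expected = np.corrcoef(resid, rowvar=False)
        iu = np.triu_indices(k, 1)
        np.testing.assert_allclose(np.tanh(cov.matrix[iu]),
                                   np.clip(expected[iu], -0.999999, 0.999999),
                                   atol=1e-10)

    def test_spearman_is_pearson_on_ranks(self):
        rng = np.random.default_rng(5)
        values = pd.DataFrame(rng.normal(size=(20, 3)))
        spearman = ts.tau_covariance(values, kind="spearman")
        pearson_on_ranks = ts.tau_covariance(values.rank(axis=0), kind="pearson")
        np.testing.assert_allclose(spearman.matrix, pearson_on_ranks.matrix,
                                   equal_nan=True)

    def test_constant_roi_set_missing(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame({"r0": rng.normal(size=8), "r1": np.ones(8),
                               "r2": rng.normal(size=8)})
        cov = ts.tau_covariance(values)
        assert np.isnan(cov.matrix[1, 0]) and np.isnan(cov.matrix[1, 2])
        assert np.isfinite(cov.matrix[0, 2])

    def test_too_few_subjects_rejected(self):
        values = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 3)))
        covs = pd.DataFrame({"age": [60.0, 61, 62, 63], "sex": list("ffmm")})
        with pytest.raises(InsufficientDataError):
            ts.tau_covariance(values, covs)


class TestCovarianceVsDistance:
    def _cov_from_matrix(self, z, n_subjects=50):
        return ts.CovarianceMatrix(matrix=z, covariates=(), n_subjects=n_subjects,
                                   correlation_kind="pearson")

    def test_exact_linear_relation_gives_minus_one(self):
        rng = np.random.default_rng(0)
        n = 12
        d = rng.uniform(1, 5, (n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        z = 2.0 - 0.3 * d
        np.fill_diagonal(z, np.nan)
        res = ts.covariance_vs_distance(self._cov_from_matrix(z), d)
        assert res.beta_std == pytest.approx(-1.0)
        assert res.n_pairs == n * (n - 1) // 2

    def test_permuted_covariance_has_no_slope(self):
        rng = np.random.default_rng(7)
        n = 200
        d = rng.uniform(1, 5, (n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        z = rng.normal(size=(n, n)); z = (z + z.T) / 2; np.fill_diagonal(z, np.nan)
        res = ts.covariance_vs_distance(self._cov_from_matrix(z), d)
        assert abs(res.beta_std) < 0.05

    def test_small_toy_matches_hand_ols(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(1, 4, (5, 5)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        z = rng.normal(0.3, 0.2, (5, 5)); z = (z + z.T) / 2
        np.fill_diagonal(z, np.nan)
        res = ts.covariance_vs_distance(self._cov_from_matrix(z), d)
        iu = np.triu_indices(5, 1)
        zz, dd = z[iu], d[iu]
        expected = np.corrcoef(dd, zz)[0, 1]
        assert res.beta_std == pytest.approx(expected)

    def test_infinite_distances_excluded(self):
        rng = np.random.default_rng(2)
        n = 10
        d = rng.uniform(1, 3, (n, n)); d = (d + d.T) / 2; np.fill_diagonal(d, 0)
        d[0, 1] = d[1, 0] = np.inf
        z = 2.0 - 0.3 * d
        z[0, 1] = z[1, 0] = 5.0
        np.fill_diagonal(z, np.nan)
        res = ts.covariance_vs_distance(self._cov_from_matrix(z), d)
        assert res.n_pairs == n * (n - 1) // 2 - 1
        assert res.beta_std == pytest.approx(-1.0)

    def test_network_scope_restricts_pairs(self, study):
        rng = np.random.default_rng(4)
        n = study.atlas.n_roi
        z = rng.normal(size=(n, n)); z = (z + z.T) / 2; np.fill_diagonal(z, np.nan)
        network = study.atlas.networks[0]
        res = ts.covariance_vs_distance(self._cov_from_matrix(z), study.distance,
                                        scope=network, atlas=study.atlas)
        m = len(study.atlas.rois_in_network(network))
        assert res.n_pairs == m * (m - 1) // 2
        assert res.scope == network

    def test_too_few_pairs_rejected(self):
        z = np.full((3, 3), 0.5); np.fill_diagonal(z, np.nan)
        d = np.ones((3, 3)); np.fill_diagonal(d, 0)
        with pytest.raises(InsufficientDataError):
            ts.covariance_vs_distance(self._cov_from_matrix(z), d)


class TestEuclideanAdjustedCovariance:
    def _cov(self, z):
        return ts.CovarianceMatrix(matrix=z, covariates=("age",), n_subjects=30,
                                   correlation_kind="pearson")

    def test_constant_euclidean_changes_nothing(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(6, 6)); z = (z + z.T) / 2; np.fill_diagonal(z, np.nan)
        out = ts.euclidean_adjusted_covariance(self._cov(z), np.ones((6, 6)))
        iu = np.triu_indices(6, 1)
        np.testing.assert_allclose(out.matrix[iu], z[iu], atol=1e-10)

    def test_linear_euclidean_component_removed(self):
        rng = np.random.default_rng(1)
        n = 8
        e = rng.uniform(10, 90, (n, n)); e = (e + e.T) / 2; np.fill_diagonal(e, 0)
        z = 0.02 * e + 0.1
        np.fill_diagonal(z, np.nan)
        out = ts.euclidean_adjusted_covariance(self._cov(z), e)
        iu = np.triu_indices(n, 1)
        # the linear component is fully removed: only the mean level remains
        np.testing.assert_allclose(out.matrix[iu], 0.1, atol=1e-10)

    def test_recovers_fc_distance_signal_under_euclidean_confound(self, study):
        n = study.atlas.n_roi
        d = study.distance.matrix
        e = ts.euclidean_distance(study.atlas)
        z = 1.0 + 0.01 * e - 0.5 * d
        np.fill_diagonal(z, np.nan)
        adjusted = ts.euclidean_adjusted_covariance(self._cov(z), e)
        res = ts.covariance_vs_distance(adjusted, study.distance)
        assert res.beta_std < -0.5


class TestNullModels:
    def _toy_graph(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        fc = rng.normal(0.2, 0.5, (n, n)); fc = (fc + fc.T) / 2
        np.fill_diagonal(fc, 0)
        return ts.threshold_density(fc, 0.3)

    def test_degree_sequence_and_weights_preserved_over_replicates(self):
        w = self._toy_graph()
        degrees = (w > 0).sum(axis=0)
        iu = np.triu_indices(w.shape[0], 1)
        weights = np.sort(w[iu][w[iu] > 0])
        for null in ts.null_models(w, B=100, seed=1):
            assert np.array_equal((null > 0).sum(axis=0), degrees)
            np.testing.assert_allclose(np.sort(null[iu][null[iu] > 0]), weights)
            assert np.array_equal(null, null.T)

    def test_rewiring_actually_shuffles_edges(self):
        w = self._toy_graph()
        null = next(ts.null_models(w, B=1, seed=2))
        assert not np.array_equal(null > 0, w > 0)

    def test_deterministic_given_seed(self):
        w = self._toy_graph()
        a = list(ts.null_models(w, B=3, seed=9))
        b = list(ts.null_models(w, B=3, seed=9))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_too_small_graph_rejected(self):
        w = np.zeros((3, 3)); w[0, 1] = w[1, 0] = 1.0
        with pytest.raises(RewireFailureError):
            next(ts.null_models(w, B=1, seed=0))


class TestExactTest:
    def test_actual_beyond_all_nulls_gives_add_one_p(self):
        nulls = np.array([-0.1, 0.05, -0.2, 0.15] * 25)  # B = 100
        out = ts.exact_test(-0.9, nulls)
        assert out.p_exact == pytest.approx(1 / 101)

    def test_zero_actual_against_symmetric_nulls_is_nonsignificant(self):
        rng = np.random.default_rng(0)
        out = ts.exact_test(0.0, rng.normal(0, 0.1, 1000))
        assert out.p_exact == pytest.approx(1.0)

    def test_hand_counted_toy(self):
        # |nulls| = {0.5, 0.3, 0.2, 0.6}; actual |beta| = 0.4 -> 2 more extreme
        out = ts.exact_test(-0.4, np.array([0.5, -0.3, 0.2, -0.6]))
        assert out.p_exact == pytest.approx((1 + 2) / 5)

    def test_magnitude_comparison_ignores_sign(self):
        nulls = np.array([0.5, 0.5, -0.5, -0.5])
        assert ts.exact_test(0.4, nulls).p_exact == ts.exact_test(-0.4, nulls).p_exact


class TestSubjectGradient:
    def test_exactly_linear_profile_gives_minus_one(self):
        d = pd.Series(np.linspace(1, 5, 40), index=range(40))
        values = pd.Series(3.0 - 0.4 * d.to_numpy(), index=range(40))
        assert ts.subject_gradient(values, d) == pytest.approx(-1.0)

    def test_monotone_decreasing_profile_is_negative(self):
        d = pd.Series(np.linspace(1, 5, 40), index=range(40))
        values = pd.Series(np.exp(-d.to_numpy()), index=range(40))
        assert ts.subject_gradient(values, d) < 0

    def test_shuffled_values_average_to_zero(self):
        rng = np.random.default_rng(0)
        d = pd.Series(np.linspace(1, 5, 100), index=range(100))
        betas = [ts.subject_gradient(
            pd.Series(rng.permutation(np.exp(-d.to_numpy())), index=range(100)), d)
            for _ in range(200)]
        assert abs(np.mean(betas)) < 0.02


class TestQuartileGradient:
    def test_one_ninety_rois_split_48_47_48_47(self):
        sizes = np.bincount(association._quartile_of_rank(190))
        assert list(sizes) == [48, 47, 48, 47]

    def test_noise_free_planted_cohort_is_strictly_decreasing(self, study,
                                                              tiny_scenario):
        import dataclasses
        from tauspread import io, connectome
        sc = dataclasses.replace(tiny_scenario,
                                 epicentre_rois=study.scenario.epicentre_rois)
        cohort, _ = ts.simulate_tau_cohort(study.distance, sc, n_subjects=6)
        wide = io.cohort_to_wide(cohort, "suvr")
        epi = np.array(sc.epicentre_rois)
        dist = connectome.epicentre_distance(study.distance, epi)
        grad = ts.quartile_gradient(wide, {s: dist for s in wide.index},
                                    value_kind="suvr")
        for _, block in grad.quartile_means.groupby("subject_id"):
            means = block.sort_values("quartile")["mean_value"].to_numpy()
            assert np.all(np.diff(means) < 0)
        assert len(grad.pairwise_tests) == 6

    def test_values_unrelated_to_distance_give_null_pvalues(self):
        rng = np.random.default_rng(3)
        n_subj, n_roi = 30, 100
        values = pd.DataFrame(rng.normal(size=(n_subj, n_roi)),
                              index=[f"s{i}" for i in range(n_subj)])
        d = pd.Series(rng.uniform(1, 5, n_roi), index=range(n_roi))
        grad = ts.quartile_gradient(values, {s: d for s in values.index})
        assert (grad.pairwise_tests["p_value"] > 0.001).all()

    def test_fewer_than_six_subjects_rejected(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(4, 40)),
                              index=[f"s{i}" for i in range(4)])
        d = pd.Series(rng.uniform(1, 5, 40), index=range(40))
        with pytest.raises(InsufficientDataError):
            ts.quartile_gradient(values, {s: d for s in values.index})
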