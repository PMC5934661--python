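import numpy as np
import pandas as pd
import pytest
from scipy import stats

import iwscoring as iw
from iwscoring.synthetic import identity_system_specs
from conftest import make_matrix
from oracles import power_iteration


class TestTransforms:
    def test_neg_log2_values(self):
        m = make_matrix([[0.25], [1.0], [np.nan]], systems=["deepsea"])
        out = iw.apply_transforms(m)
        assert out.values[0, 0] == pytest.approx(2.0)
        assert out.values[1, 0] == pytest.approx(0.0)
        assert np.isnan(out.values[2, 0])

    def test_p_floor_bounds_tiny_p(self):
        m = make_matrix([[1e-300], [0.5]], systems=["deepsea"])
        out = iw.apply_transforms(m, p_floor=1e-16)
        assert out.values[0, 0] == pytest.approx(-np.log2(1e-16))
        assert out.values[0, 0] == pytest.approx(53.1508, abs=1e-3)

    def test_identity_columns_untouched(self):
        m = make_matrix([[5.0], [-3.0]], systems=["cadd"])
        np.testing.assert_array_equal(iw.apply_transforms(m).values, m.values)

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_out_of_range_p_rejected(self, bad):
        m = make_matrix([[bad], [0.5]], systems=["deepsea"])
        with pytest.raises(iw.ValidationError, match="deepsea"):
            iw.apply_transforms(m)


class TestStandardize:
    def test_three_point_column(self):
        m = make_matrix([[1.0], [2.0], [3.0]], systems=["cadd"])
        out, params = iw.standardize_training(m)
        np.testing.assert_allclose(out.values[:, 0], [-1.0, 0.0, 1.0])
        p = params["cadd"]
        assert (p.min_a, p.max_a) == (1.0, 3.0)
        assert (p.min_r, p.max_r) == pytest.approx((-1.0, 1.0))
        assert (p.mean, p.sd) == (2.0, 1.0)

    def test_binary_column_sample_sd(self):
        m = make_matrix([[0.0], [0.0], [1.0], [1.0]], systems=["cadd"])
        out, params = iw.standardize_training(m)
        assert params["cadd"].mean == pytest.approx(0.5)
        assert params["cadd"].sd == pytest.approx(0.57735, abs=1e-5)
        np.testing.assert_allclose(
            out.values[:, 0], [-0.8660254, -0.8660254, 0.8660254, 0.8660254], atol=1e-6)

    def test_constant_column_names_system(self):
        m = make_matrix([[5.0], [5.0], [5.0]], systems=["fitcons"])
        with pytest.raises(iw.ValidationError, match="zero variance: fitcons"):
            iw.standardize_training(m)

    def test_standardized_mean_zero_var_one_with_missing(self, rng):
        vals = rng.standard_normal((500, 3)) * 5 + 2
        vals[rng.random((500, 3)) < 0.2] = np.nan
        out, _ = iw.standardize_training(make_matrix(vals))
        for j in range(3):
            col = out.values[:, j]
            col = col[~np.isnan(col)]
            assert abs(col.mean()) < 1e-10
            assert abs(col.var(ddof=1) - 1) < 1e-10


class TestPairwiseCorrelation:
    def test_identical_columns_give_one(self, rng):
        x = rng.standard_normal(50)
        corr = iw.pairwise_correlation(make_matrix(np.column_stack([x, x])))
        assert corr.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(42)
        corr = iw.pairwise_correlation(make_matrix(rng.standard_normal((10_000, 2))))
        assert abs(corr.iloc[0, 1]) < 0.05

    def test_matches_complete_case_oracle_under_missingness(self, rng):
        vals = rng.standard_normal((200, 4))
        vals[:, 1] += 0.8 * vals[:, 0]
        vals[rng.random((200, 4)) < 0.25] = np.nan
        corr = iw.pairwise_correlation(make_matrix(vals))
        for i in range(4):
            for j in range(i + 1, 4):
                joint = ~np.isnan(vals[:, i]) & ~np.isnan(vals[:, j])
                expected = np.corrcoef(vals[joint, i], vals[joint, j])[0, 1]
                assert corr.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_too_few_joint_observations_rejected(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan], [np.nan, 1.0],
                         [np.nan, 2.0], [3.0, 3.0], [4.0, 5.0]])
        with pytest.raises(iw.ValidationError, match="s0.*s1"):
            iw.pairwise_correlation(make_matrix(vals))


class TestEstimateWeights:
    def test_two_system_exchangeable(self):
        w = iw.estimate_weights(np.array([[1.0, 0.8], [0.8, 1.0]]))
        np.testing.assert_allclose(w.values, [0.70710678, 0.70710678], atol=1e-8)
        assert w.lead_eigenvalue == pytest.approx(1.8)

    def test_two_block_three_systems(self):
        mat = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.0], [0.0, 0.0, 1.0]])
        w = iw.estimate_weights(mat)
        np.testing.assert_allclose(w.values, [0.70710678, 0.70710678, 0.0], atol=1e-8)
        assert w.lead_eigenvalue == pytest.approx(1.9)

    @pytest.mark.parametrize("k", [2, 5, 11])
    @pytest.mark.parametrize("r", [0.1, 0.5, 0.9])
    def test_exchangeable_weights_exact(self, k, r):
        mat = np.full((k, k), r)
        np.fill_diagonal(mat, 1.0)
        w = iw.estimate_weights(mat)
        np.testing.assert_allclose(w.values, np.full(k, 1 / np.sqrt(k)), atol=1e-12)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_power_iteration(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((60, 7))
        corr = np.corrcoef(data, rowvar=False)
        w = iw.estimate_weights(corr)
        v, lam = power_iteration(corr)
        if v @ w.values < 0:
            v = -v
        assert np.abs(v - w.values).max() < 1e-8
        assert lam == pytest.approx(w.lead_eigenvalue, abs=1e-8)
        assert np.linalg.norm(w.values) == pytest.approx(1.0, abs=1e-10)

    def test_permutation_equivariance(self, rng):
        data = rng.standard_normal((100, 5))
        data[:, 2] += data[:, 0]
        corr = np.corrcoef(data, rowvar=False)
        w = iw.estimate_weights(corr).values
        perm = [3, 0, 4, 1, 2]
        wp = iw.estimate_weights(corr[np.ix_(perm, perm)]).values
        np.testing.assert_allclose(wp, w[perm], atol=1e-10)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(iw.ValidationError, match="symmetric"):
            iw.estimate_weights(np.array([[1.0, 0.5], [0.2, 1.0]]))

    def test_tied_lead_eigenvalue_rejected(self):
        with pytest.raises(iw.ValidationError, match="tied"):
            iw.estimate_weights(np.eye(3))


class TestFitNull:
    def test_recovers_shifted_lognormal_parameters(self):
        rng = np.random.default_rng(1)
        scores = np.exp(rng.standard_normal(100_000)) - 1.0
        null = iw.fit_null(scores)
        assert abs(null.meanlog - 0.0) < 0.02
        assert abs(null.sdlog - 1.0) < 0.02

    def test_median_maps_near_half(self):
        rng = np.random.default_rng(2)
        scores = rng.gamma(2.0, 1.5, size=5000) - 2.0
        null = iw.fit_null(scores)
        assert 0.45 <= null.p_value(float(np.median(scores))) <= 0.55

    def test_empirical_tail_rank_convention(self):
        rng = np.random.default_rng(3)
        scores = rng.standard_normal(1000)
        null = iw.fit_null(scores, family="empirical")
        n = len(scores)
        assert null.p_value(scores.max() + 10) == pytest.approx(1 / (n + 1))
        assert null.p_value(scores.min() - 10) == pytest.approx(1.0)

    def test_p_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(4)
        scores = rng.standard_normal(2000) * 2
        grid = np.linspace(scores.min() - 1, scores.max() + 1, 200)
        for family in ("shifted_lognormal", "empirical"):
            null = iw.fit_null(scores, family=family)
            p = null.p_value(grid)
            assert np.all(np.diff(p) <= 1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(iw.ValidationError):
            iw.fit_null(np.ones(500))
        with pytest.raises(iw.ValidationError):
            iw.fit_null(np.arange(50, dtype=float))


class TestTrain:
    def test_same_seed_bit_identical(self, small_model):
        model, matrix, _ = small_model
        again = iw.train(matrix, "K11", seed=7, reference_size=1500,
                         system_specs=identity_system_specs(matrix.systems))
        np.testing.assert_array_equal(again.weights.values, model.weights.values)
        np.testing.assert_array_equal(again.reference_pool, model.reference_pool)
        np.testing.assert_array_equal(again.null.sorted_scores, model.null.sorted_scores)
        assert again.null.meanlog == model.null.meanlog

    def test_k10_excludes_fitcons(self, small_model):
        _, matrix, _ = small_model
        model = iw.train(matrix, "K10", seed=1, reference_size=500,
                         system_specs=identity_system_specs(matrix.systems))
        assert len(model.systems) == 10
        assert "fitcons" not in model.systems
        assert set(model.rescale_params) == set(model.systems)
        assert model.weights.systems == model.systems

    def test_reference_pool_is_complete_case(self, small_model):
        model, _, _ = small_model
        assert not np.isnan(model.reference_pool).any()
        assert model.reference_pool.shape[1] == len(model.systems)


class TestWeightStability:
    def test_full_fraction_zero_deviation(self, small_model):
        _, matrix, _ = small_model
        report = iw.weight_stability(matrix, fractions=[1.0], n_repeats=2, seed=0,
                                     system_specs=identity_system_specs(matrix.systems))
        assert (report["max_abs_dev"] == 0).all()

    def test_report_shape(self, small_model):
        _, matrix, _ = small_model
        report = iw.weight_stability(matrix, fractions=[0.5, 0.8], n_repeats=3, seed=0,
                                     system_specs=identity_system_specs(matrix.systems))
        assert len(report) == 6
        assert {"fraction", "repeat", "max_abs_dev", "ok"} <= set(report.columns)

    def test_bad_fraction_rejected(self, small_model):
        _, matrix, _ = small_model
        with pytest.raises(iw.ValidationError):
            iw.weight_stability(matrix, fractions=[0.0], n_repeats=1)
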