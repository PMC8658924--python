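"""Unit and property tests for the PCA-based feature-extraction stages."""

import numpy as np
import pytest

from pcafe.core_fe import (
    NO_COMPONENT_STATUS,
    associate_components_with_time,
    decompose,
    run_pca_fe,
    score_probes,
    standardize,
)
from pcafe.io_geo import ExpressionMatrix
from pcafe.synthetic import SyntheticSpec, generate

from conftest import random_expression_matrix


def matrix_from_values(values, times=None):
    values = np.asarray(values, dtype=float)
    n, s = values.shape
    if times is None:
        times = np.arange(1, s + 1, dtype=float)
    return ExpressionMatrix(
        values=values,
        probe_ids=[f"p{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(s)],
        condition=["treated"] * s,
        time_h=times,
    )


class TestStandardize:
    def test_three_point_column(self):
        m = matrix_from_values(np.array([[1.0], [2.0], [3.0]]), times=[1.0])
        sm = standardize(m)
        expected = np.array([-1.224744871391589, 0.0, 1.224744871391589])
        np.testing.assert_allclose(sm.values[:, 0], expected, atol=1e-12)
        assert sm.values[:, 0].sum() == pytest.approx(0.0, abs=1e-12)
        assert (sm.values[:, 0] ** 2).sum() == pytest.approx(3.0, abs=1e-12)

    def test_column_invariants_on_random_matrix(self):
        rng = np.random.default_rng(0)
        m = random_expression_matrix(rng, n_probes=100, n_samples=9)
        sm = standardize(m)
        np.testing.assert_allclose(sm.values.sum(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(
            (sm.values**2).sum(axis=0), 100.0, atol=1e-6
        )

    def test_idempotent_on_standardized_input(self):
        rng = np.random.default_rng(1)
        m = random_expression_matrix(rng, n_probes=50, n_samples=5)
        sm = standardize(m)
        m2 = matrix_from_values(sm.values, times=m.time_h)
        sm2 = standardize(m2)
        np.testing.assert_allclose(sm2.values, sm.values, atol=1e-12)

    def test_zero_variance_column_names_sample(self):
        values = np.ones((5, 2))
        values[:, 0] = [1, 2, 3, 4, 5]
        m = matrix_from_values(values)
        with pytest.raises(ValueError, match="s1"):
            standardize(m)

    def test_metadata_passed_through(self, small_matrix):
        sm = standardize(small_matrix)
        assert sm.probe_ids == small_matrix.probe_ids
        assert sm.sample_ids == small_matrix.sample_ids
        np.testing.assert_array_equal(sm.time_h, small_matrix.time_h)


class TestDecompose:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=40)
        u /= np.linalg.norm(u)
        v = rng.normal(size=6)
        v /= np.linalg.norm(v)
        m = 5.0 * np.outer(u, v)
        d = _decompose_raw(m)
        assert d.singular_values[0] == pytest.approx(5.0, abs=1e-10)
        assert np.all(d.singular_values[1:] < 1e-10)

    def test_reconstruction_and_orthogonality(self):
        rng = np.random.default_rng(3)
        m = random_expression_matrix(rng, n_probes=50, n_samples=7)
        sm = standardize(m)
        d = decompose(sm)
        recon = d.probe_scores @ np.diag(d.singular_values) @ d.sample_loadings.T
        rel_err = np.linalg.norm(recon - sm.values) / np.linalg.norm(sm.values)
        assert rel_err < 1e-10
        k = d.singular_values.size
        np.testing.assert_allclose(
            d.probe_scores.T @ d.probe_scores, np.eye(k), atol=1e-10
        )
        np.testing.assert_allclose(
            d.sample_loadings.T @ d.sample_loadings, np.eye(k), atol=1e-10
        )
        assert np.all(np.diff(d.singular_values) <= 1e-12)

    def test_sign_convention_largest_entry_positive(self):
        rng = np.random.default_rng(4)
        m = random_expression_matrix(rng, n_probes=30, n_samples=5)
        d = decompose(standardize(m))
        for ell in range(d.n_components):
            col = d.probe_scores[:, ell]
            assert col[np.argmax(np.abs(col))] > 0

    def test_probe_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        m = random_expression_matrix(rng, n_probes=30, n_samples=5)
        perm = rng.permutation(30)
        m_perm = ExpressionMatrix(
            values=m.values[perm],
            probe_ids=[m.probe_ids[i] for i in perm],
            sample_ids=m.sample_ids,
            condition=m.condition,
            time_h=m.time_h,
        )
        d = decompose(standardize(m))
        d_perm = decompose(standardize(m_perm))
        np.testing.assert_allclose(
            d_perm.singular_values, d.singular_values, atol=1e-10
        )
        np.testing.assert_allclose(
            np.abs(d_perm.sample_loadings), np.abs(d.sample_loadings), atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(d_perm.probe_scores), np.abs(d.probe_scores[perm]), atol=1e-8
        )

    def test_non_finite_rejected(self):
        sm_values = np.zeros((3, 2))
        sm_values[0, 0] = np.nan
        with pytest.raises(ValueError):
            _decompose_raw(sm_values)


def _decompose_raw(values):
    """Decompose arbitrary values by bypassing column-standardization checks."""
    from pcafe.core_fe import StandardizedMatrix

    values = np.asarray(values, dtype=float)
    sm = StandardizedMatrix.__new__(StandardizedMatrix)
    sm.values = values
    sm.probe_ids = [f"p{i}" for i in range(values.shape[0])]
    sm.sample_ids = [f"s{j}" for j in range(values.shape[1])]
    sm.condition = ["treated"] * values.shape[1]
    sm.time_h = np.arange(1.0, values.shape[1] + 1)
    return decompose(sm)


class TestAssociateComponents:
    def test_loading_proportional_to_time_is_selected(self):
        times = np.array([1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 48.0])
        rng = np.random.default_rng(6)
        d = _decompose_raw(rng.normal(size=(30, 7)))
        d.sample_loadings[:, 0] = 0.3 * times + 1.0
        assocs = associate_components_with_time(d, times)
        assert assocs[0].p_value < 1e-10
        assert assocs[0].selected

    def test_loading_orthogonal_to_centered_time_has_p_one(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        d = _decompose_raw(np.random.default_rng(7).normal(size=(20, 4)))
        # constant loading: slope exactly 0
        d.sample_loadings[:, 1] = 0.5
        assocs = associate_components_with_time(d, times)
        assert assocs[1].slope == pytest.approx(0.0, abs=1e-12)
        assert assocs[1].p_value == pytest.approx(1.0, abs=1e-9)

    def test_bh_is_across_all_components(self):
        rng = np.random.default_rng(8)
        times = np.array([1.0, 2.0, 4.0, 8.0, 12.0])
        d = _decompose_raw(rng.normal(size=(20, 5)))
        assocs = associate_components_with_time(d, times)
        from pcafe.stats import bh_adjust

        expected = bh_adjust([a.p_value for a in assocs])
        np.testing.assert_allclose(
            [a.adjusted_p for a in assocs], expected, atol=1e-15
        )
        for a in assocs:
            assert a.adjusted_p >= a.p_value - 1e-15
            assert a.selected == (a.adjusted_p < 0.05)

    def test_identical_times_rejected(self):
        d = _decompose_raw(np.random.default_rng(9).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="identical"):
            associate_components_with_time(d, [2.0, 2.0, 2.0, 2.0])

    def test_component_indices_are_one_based(self):
        d = _decompose_raw(np.random.default_rng(10).normal(size=(10, 4)))
        assocs = associate_components_with_time(d, [1.0, 2.0, 4.0, 8.0])
        assert [a.component for a in assocs] == [1, 2, 3, 4]


class TestScoreProbes:
    def test_zero_score_probe_has_p_one(self):
        d = _decompose_raw(np.random.default_rng(11).normal(size=(20, 4)))
        d.probe_scores[5, 0] = 0.0
        table = score_probes(d, [1])
        assert table.statistic[5] == 0.0
        assert table.p_value[5] == 1.0
        assert table.df == 1

    def test_chi2_quantile_example(self):
        # a probe whose standardized squared score is the 5% critical value
        d = _decompose_raw(np.random.default_rng(12).normal(size=(50, 4)))
        u = d.probe_scores[:, 0]
        sigma = float(np.sqrt(np.mean(u**2)))
        d.probe_scores[7, 0] = sigma * np.sqrt(3.841459)
        table = score_probes(d, [1])
        # sigma shifts slightly after editing one entry; recompute statistic
        new_sigma = float(np.sqrt(np.mean(d.probe_scores[:, 0] ** 2)))
        expected_stat = (d.probe_scores[7, 0] / new_sigma) ** 2
        assert table.statistic[7] == pytest.approx(expected_stat, rel=1e-12)
        from pcafe.stats import chi2_upper_tail

        assert table.p_value[7] == pytest.approx(
            chi2_upper_tail(expected_stat, 1), rel=1e-12
        )

    def test_statistic_sums_over_selected_components(self):
        d = _decompose_raw(np.random.default_rng(13).normal(size=(30, 5)))
        table = score_probes(d, [1, 3])
        s1 = d.probe_scores[:, 0] / table.sigma[1]
        s3 = d.probe_scores[:, 2] / table.sigma[3]
        np.testing.assert_allclose(table.statistic, s1**2 + s3**2, rtol=1e-12)
        assert table.df == 2

    def test_sigma_modes_agree_closely_for_centered_scores(self):
        d = _decompose_raw(np.random.default_rng(14).normal(size=(200, 6)))
        rms = score_probes(d, [2], sigma_mode="rms")
        sd = score_probes(d, [2], sigma_mode="sd")
        np.testing.assert_allclose(rms.statistic, sd.statistic, rtol=0.05)

    def test_empty_component_list_is_error(self):
        d = _decompose_raw(np.random.default_rng(15).normal(size=(10, 4)))
        with pytest.raises(ValueError, match="no time-associated component"):
            score_probes(d, [])

    def test_monotone_p_in_statistic(self):
        d = _decompose_raw(np.random.default_rng(16).normal(size=(100, 5)))
        table = score_probes(d, [1])
        order = np.argsort(table.statistic)
        assert np.all(np.diff(table.p_value[order]) <= 1e-15)


class TestRunPcaFe:
    def test_planted_signal_recovered_structurally(self):
        spec = SyntheticSpec(n_probes=500, seed=123)
        treated, _, truth = generate(spec)
        result = run_pca_fe(treated)
        assert result.status == "ok"
        assert result.selected_components
        selected = set(result.selected_probe_ids)
        assert selected
        # selected probes are overwhelmingly planted
        assert len(selected & truth.planted_probe_ids) / len(selected) > 0.8

    def test_no_component_status(self):
        # constant-in-time structure only: no loading correlates with time
        rng = np.random.default_rng(17)
        m = random_expression_matrix(rng, n_probes=60, n_samples=6)
        # overwrite times so any apparent trend is broken by symmetry
        result = run_pca_fe(m, alpha_component=1e-12)
        assert result.status == NO_COMPONENT_STATUS
        assert result.scores is None
        assert result.selected_probe_ids == []

    def test_single_component_restriction(self):
        spec = SyntheticSpec(n_probes=500, seed=3)
        treated, _, _ = generate(spec)
        result = run_pca_fe(treated, alpha_component=0.9, single_component=True)
        if result.status == "ok":
            assert len(result.scores.sigma) == 1


class TestPipelineInvariants:
    def _run(self, m):
        return run_pca_fe(m, alpha_component=0.5)

    def test_sign_flip_invariance(self):
        rng = np.random.default_rng(18)
        m = random_expression_matrix(rng, n_probes=80, n_samples=7)
        d = decompose(standardize(m))
        table = score_probes(d, [1, 2])
        d.probe_scores[:, 0] *= -1
        d.sample_loadings[:, 0] *= -1
        flipped = score_probes(d, [1, 2])
        np.testing.assert_allclose(flipped.p_value, table.p_value, rtol=1e-12)
        np.testing.assert_allclose(
            flipped.adjusted_p, table.adjusted_p, rtol=1e-12
        )
        np.testing.assert_array_equal(flipped.selected, table.selected)
        assocs = associate_components_with_time(d, m.time_h)
        d.sample_loadings[:, 1] *= -1
        assocs_flipped = associate_components_with_time(d, m.time_h)
        np.testing.assert_allclose(
            [a.p_value for a in assocs_flipped],
            [a.p_value for a in assocs],
            rtol=1e-9,
        )

    def test_global_scale_invariance(self):
        spec = SyntheticSpec(n_probes=300, seed=21)
        treated, _, _ = generate(spec)
        scaled = ExpressionMatrix(
            values=treated.values * 37.5,
            probe_ids=treated.probe_ids,
            sample_ids=treated.sample_ids,
            condition=treated.condition,
            time_h=treated.time_h,
        )
        base = self._run(treated)
        other = self._run(scaled)
        assert base.status == other.status
        assert base.selected_components == other.selected_components
        if base.scores is not None:
            np.testing.assert_allclose(
                other.scores.p_value, base.scores.p_value, rtol=1e-8
            )
            assert base.selected_probe_ids == other.selected_probe_ids

    def test_probe_permutation_equivariance(self):
        spec = SyntheticSpec(n_probes=300, seed=22)
        treated, _, _ = generate(spec)
        rng = np.random.default_rng(0)
        perm = rng.permutation(treated.n_probes)
        permuted = ExpressionMatrix(
            values=treated.values[perm],
            probe_ids=[treated.probe_ids[i] for i in perm],
            sample_ids=treated.sample_ids,
            condition=treated.condition,
            time_h=treated.time_h,
        )
        base = self._run(treated)
        other = self._run(permuted)
        assert set(base.selected_probe_ids) == set(other.selected_probe_ids)

    def test_selected_statistics_dominate_unselected(self):
        spec = SyntheticSpec(n_probes=400, seed=23)
        treated, _, _ = generate(spec)
        result = self._run(treated)
        assert result.scores is not None and result.scores.n_selected > 0
        sel = result.scores.selected
        assert result.scores.statistic[sel].min() >= (
            result.scores.statistic[~sel].max() if (~sel).any() else -np.inf
        )
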