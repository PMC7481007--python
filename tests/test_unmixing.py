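"""Mutual-information unmixing: estimator, mixing fit, subspaces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lpfc_subspaces.datasets import ConditionMatrix
from lpfc_subspaces.simulate import ParametricGroundTruth, generate_parametric_dataset
from lpfc_subspaces.unmixing import (
    MutualInfoUnmixer,
    build_subspace,
    fit_mixing,
    gram_schmidt_subspaces,
    mutual_information,
    sturges_bins,
    unmix_pair,
    unmix_presaccade,
    unmix_single_trials,
    unmix_error_trials,
    unmix_uncorrelated,
)


class TestSturges:
    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 2), (1000, 11), (1582, 12)])
    def test_bin_counts(self, n, expected):
        assert sturges_bins(n) == expected

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sturges_bins(0)


class TestMutualInformation:
    def test_identical_two_level_arrays_give_one_bit(self):
        assert mutual_information([1, 1, 2, 2], [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_independent_uniform_pairs_give_zero(self):
        assert mutual_information([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=200), rng.normal(size=200)
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))

    def test_constant_array_is_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.ones(10), np.arange(10.0)) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        scale=st.floats(0.1, 100.0),
        shift=st.floats(-50.0, 50.0),
    )
    def test_affine_invariance_and_nonnegativity(self, seed, scale, shift):
        """Bins are range-relative, so affine maps leave MI unchanged."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300)
        y = 0.5 * x + rng.normal(size=300)
        base = mutual_information(x, y)
        assert base >= 0.0
        assert mutual_information(scale * x + shift, y) == pytest.approx(base, abs=1e-9)

    def test_equal_frequency_binning_option(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=500)
        assert mutual_information(x, x, binning="frequency") > 1.0


class TestUnmixPair:
    def test_zero_coefficients_are_identity(self):
        rng = np.random.default_rng(0)
        d1, d2 = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        m, p = unmix_pair(d1, d2, 0.0, 0.0)
        np.testing.assert_array_equal(m, d1)
        np.testing.assert_array_equal(p, d2)

    def test_exact_recovery_by_construction(self):
        rng = np.random.default_rng(1)
        m_true, p_true = rng.normal(size=(50, 7)), rng.normal(size=(50, 7))
        a, b = 0.12, 0.65
        m, p = unmix_pair(m_true + a * p_true, b * m_true + p_true, a, b)
        np.testing.assert_allclose(m, m_true, atol=1e-12)
        np.testing.assert_allclose(p, p_true, atol=1e-12)

    def test_singular_mixing_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            unmix_pair(np.ones((2, 2)), np.ones((2, 2)), 2.0, 0.5)

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_remix_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        d1, d2 = rng.normal(size=(20, 5)), rng.normal(size=(20, 5))
        a, b = rng.uniform(-0.5, 1.5, 2)
        if abs(1 - a * b) < 0.05:
            return
        m, p = unmix_pair(d1, d2, a, b)
        np.testing.assert_allclose(m + a * p, d1, atol=1e-10)
        np.testing.assert_allclose(b * m + p, d2, atol=1e-10)


class TestFitMixing:
    def test_recovers_parametric_ground_truth(self):
        gt = ParametricGroundTruth(a=0.2, b=0.5)
        d1, d2, _, _ = generate_parametric_dataset(gt, seed=0)
        sol = fit_mixing(d1, d2, n_restarts=60, seed=0)
        assert sol.a == pytest.approx(0.2, abs=0.1)
        assert sol.b == pytest.approx(0.5, abs=0.1)
        assert sol.mi_min <= sol.mi_original

    def test_identical_matrices_flagged_degenerate(self):
        rng = np.random.default_rng(2)
        d1 = rng.normal(size=(30, 7))
        sol = fit_mixing(d1, d1.copy(), n_restarts=20, seed=0)
        assert sol.degenerate
        assert (sol.a, sol.b) == (0.0, 0.0)

    def test_restart_statistics_recorded(self):
        gt = ParametricGroundTruth(n_neurons=40, n_conditions=5)
        d1, d2, _, _ = generate_parametric_dataset(gt, seed=3)
        sol = fit_mixing(d1, d2, n_restarts=25, seed=1)
        assert sol.restarts.shape == (25, 3)
        assert sol.a_sd_all >= 0 and sol.b_sd_all >= 0
        assert sol.a_rounded == round(sol.a, 2)


class TestBuildSubspace:
    def test_orthonormal_input_spans_same_space(self):
        q, _ = np.linalg.qr(np.random.default_rng(0).normal(size=(10, 3)))
        sub = build_subspace(q)
        assert sub.dim == 3
        np.testing.assert_allclose(sub.basis @ (sub.basis.T @ q), q, atol=1e-10)

    def test_rank_detection(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(20, 3))
        element = base @ rng.normal(size=(3, 7))  # rank-3, 7 columns
        assert build_subspace(element).dim == 3

    def test_paper_shape_full_rank(self):
        rng = np.random.default_rng(2)
        element = rng.normal(size=(226, 7))
        sub = build_subspace(element)
        assert sub.dim == 7
        np.testing.assert_allclose(sub.basis.T @ sub.basis, np.eye(7), atol=1e-10)

    def test_projector_matches_svd_oracle(self):
        rng = np.random.default_rng(3)
        element = rng.normal(size=(15, 4))
        sub = build_subspace(element)
        u, s, _ = np.linalg.svd(element, full_matrices=False)
        oracle = u[:, : np.sum(s > 1e-8 * s[0])]
        np.testing.assert_allclose(
            sub.basis @ sub.basis.T, oracle @ oracle.T, atol=1e-10
        )

    def test_zero_element_rejected(self):
        with pytest.raises(ValueError):
            build_subspace(np.zeros((5, 3)))


class TestSingleTrialUnmixing:
    def _fixture(self, a=0.3, b=0.7):
        rng = np.random.default_rng(4)
        labels = np.arange(1, 4)
        m = ConditionMatrix(rng.normal(size=(10, 3)), labels)
        p = ConditionMatrix(rng.normal(size=(10, 3)), labels)
        trial_labels = np.repeat(labels, 5)
        cols = np.searchsorted(labels, trial_labels)
        d1 = (m.values + a * p.values)[:, cols]
        d2 = (b * m.values + p.values)[:, cols]
        return m, p, d1, d2, trial_labels, a, b

    def test_noise_free_algebra(self):
        m, p, d1, d2, labels, a, b = self._fixture()
        m1, m2, p1, p2 = unmix_single_trials(d1, d2, labels, m, p, a, b)
        cols = np.searchsorted(np.arange(1, 4), labels)
        np.testing.assert_allclose(m2, (b * m.values)[:, cols], atol=1e-12)
        np.testing.assert_allclose(p1, (a * p.values)[:, cols], atol=1e-12)
        np.testing.assert_allclose(m1, m.values[:, cols], atol=1e-12)
        np.testing.assert_allclose(p2, p.values[:, cols], atol=1e-12)

    def test_zero_a_leaves_d1_unchanged(self):
        m, p, d1, d2, labels, _, b = self._fixture()
        m1, _, _, _ = unmix_single_trials(d1, d2, labels, m, p, 0.0, b)
        np.testing.assert_array_equal(m1, d1)

    def test_unknown_label_rejected(self):
        m, p, d1, d2, labels, a, b = self._fixture()
        bad = labels.copy()
        bad[0] = 99
        with pytest.raises(KeyError):
            unmix_single_trials(d1, d2, bad, m, p, a, b)

    def test_error_trials_same_machinery(self):
        m, p, d1, d2, labels, a, b = self._fixture()
        out1 = unmix_single_trials(d1, d2, labels, m, p, a, b)
        out2 = unmix_error_trials(d1, d2, labels, m, p, a, b)
        for x, y in zip(out1, out2):
            np.testing.assert_array_equal(x, y)


class TestPresaccadeUnmixing:
    def test_presaccade_element_matches_construction(self):
        """If pre-saccade activity is the preparation element plus noise,
        the second unmixed element must correlate strongly with it."""
        rng = np.random.default_rng(5)
        labels = np.arange(1, 8)
        m_true = rng.lognormal(0, 1, size=(100, 7))
        p_true = rng.lognormal(0, 1, size=(100, 7))
        d1 = ConditionMatrix(m_true + 0.1 * p_true, labels)
        ds = ConditionMatrix(p_true + 0.7 * m_true + 0.05 * rng.normal(size=(100, 7)), labels)
        sol, m_prime, s_bar = unmix_presaccade(d1, ds, n_restarts=40, seed=0)
        r = np.corrcoef(s_bar.values.ravel(), p_true.ravel())[0, 1]
        assert r > 0.9

    def test_zero_coefficient_identity(self):
        rng = np.random.default_rng(6)
        labels = np.arange(1, 4)
        d1 = ConditionMatrix(rng.normal(size=(20, 3)), labels)
        ds = ConditionMatrix(rng.normal(size=(20, 3)), labels)
        m, p = unmix_pair(d1, ds, 0.0, 0.0)
        np.testing.assert_array_equal(m.values, d1.values)
        np.testing.assert_array_equal(p.values, ds.values)


class TestUncorrelatedUnmixing:
    def test_one_to_one_reduces_to_unmix_pair(self):
        rng = np.random.default_rng(7)
        labels = np.arange(1, 5)
        l_true = rng.lognormal(0, 1, size=(60, 4))
        c_true = rng.lognormal(0, 1, size=(60, 4))
        a, b = 0.15, 0.6
        g1 = ConditionMatrix(l_true + a * c_true, labels)
        g2 = ConditionMatrix(c_true + b * l_true, labels)
        trial_l = np.repeat(labels, 30)
        trial_c = trial_l.copy()  # one-to-one mapping
        l_est, c_est, sol = unmix_uncorrelated(
            g1, g2, trial_l, trial_c, n_restarts=30, grid_step=0.1, seed=0
        )
        m_pair, p_pair = unmix_pair(g1, g2, sol.a, sol.b)
        np.testing.assert_allclose(l_est.values, m_pair.values, atol=1e-6)
        np.testing.assert_allclose(c_est.values, p_pair.values, atol=1e-6)

    def test_fully_crossed_zero_translation_skips_optimization(self):
        rng = np.random.default_rng(8)
        l_labels = np.arange(1, 3)
        c_labels = np.arange(1, 4)
        # zero-mean columns: averaging over the other variable nets zero
        l_mat = rng.normal(size=(40, 2))
        c_mat = rng.normal(size=(40, 3))
        c_mat -= c_mat.mean(axis=1, keepdims=True)
        l_mat -= l_mat.mean(axis=1, keepdims=True)
        g1 = ConditionMatrix(l_mat, l_labels)
        g2 = ConditionMatrix(c_mat, c_labels)
        trial_l = np.tile(np.repeat(l_labels, 3), 10)
        trial_c = np.tile(c_labels, 20)
        l_est, c_est, sol = unmix_uncorrelated(g1, g2, trial_l, trial_c, seed=0)
        assert (sol.a, sol.b) == (0.0, 0.0)
        np.testing.assert_array_equal(l_est.values, l_mat)
        np.testing.assert_array_equal(c_est.values, c_mat)

    def test_crossed_design_recovery(self):
        rng = np.random.default_rng(9)
        labels = np.arange(1, 4)
        l_true = rng.lognormal(0, 1, size=(80, 3))
        c_true = rng.lognormal(0, 1, size=(80, 3))
        a, b = 0.1, 0.6
        # fully crossed labels with equal frequency -> E[C|L] = column mean
        e_c = c_true.mean(axis=1, keepdims=True) @ np.ones((1, 3))
        e_l = l_true.mean(axis=1, keepdims=True) @ np.ones((1, 3))
        g1 = ConditionMatrix(l_true + a * e_c, labels)
        g2 = ConditionMatrix(c_true + b * e_l, labels)
        trial_l = np.tile(np.repeat(labels, 3), 12)
        trial_c = np.tile(labels, 36)
        l_est, c_est, sol = unmix_uncorrelated(
            g1, g2, trial_l, trial_c, n_restarts=20, grid_step=0.1, seed=0
        )
        assert sol.mi_min <= sol.mi_original
        r = np.corrcoef(l_est.values.ravel(), l_true.ravel())[0, 1]
        assert r > 0.99


class TestGramSchmidt:
    def test_outputs_exactly_orthogonal(self):
        rng = np.random.default_rng(10)
        d1, d2 = rng.normal(size=(30, 5)), rng.normal(size=(30, 5))
        s1, s2 = gram_schmidt_subspaces(d1, d2)
        cross = np.linalg.svd(s1.basis.T @ s2.basis, compute_uv=False)
        np.testing.assert_allclose(cross, 0.0, atol=1e-10)

    def test_already_orthogonal_d2_preserved(self):
        d1 = np.eye(6)[:, :2]
        d2 = np.eye(6)[:, 3:5]
        s1, s2 = gram_schmidt_subspaces(d1, d2)
        np.testing.assert_allclose(
            s2.basis @ s2.basis.T @ d2, d2, atol=1e-10
        )

    def test_d2_inside_span_d1_rejected(self):
        rng = np.random.default_rng(11)
        d1 = rng.normal(size=(10, 4))
        d2 = d1 @ rng.normal(size=(4, 4))
        with pytest.raises(ValueError, match="inside span"):
            gram_schmidt_subspaces(d1, d2)

    def test_small_a_makes_gram_schmidt_close_to_mi_subspaces(self):
        """With little preparation activity in Delay 1 the two constructions
        nearly coincide (small leading principal angles)."""
        from lpfc_subspaces.geometry import principal_angles

        gt = ParametricGroundTruth(a=0.02, b=0.6, n_neurons=120)
        d1, d2, _, _ = generate_parametric_dataset(gt, seed=4)
        est = MutualInfoUnmixer(n_restarts=40, random_state=0).fit(d1, d2)
        g1, g2 = gram_schmidt_subspaces(d1.values, d2.values)
        angles = principal_angles(est.memory_subspace_, g1).angles
        assert angles[0] < 10.0


class TestEstimatorInterface:
    def test_fit_sets_sklearn_style_attributes(self):
        gt = ParametricGroundTruth(n_neurons=60, n_conditions=5)
        d1, d2, _, _ = generate_parametric_dataset(gt, seed=5)
        est = MutualInfoUnmixer(n_restarts=15, random_state=0)
        assert est.get_params()["n_restarts"] == 15
        est.fit(d1, d2)
        for attr in ("a_", "b_", "mi_min_", "memory_subspace_", "preparation_subspace_"):
            assert hasattr(est, attr)

    def test_transform_matches_function(self):
        gt = ParametricGroundTruth(n_neurons=30, n_conditions=4, noise_sd=0.2)
        d1, d2, p1, p2 = generate_parametric_dataset(gt, seed=6)
        est = MutualInfoUnmixer(n_restarts=15, random_state=0).fit(d1, d2)
        m1, m2, pp1, pp2 = est.transform(p1.train, p2.train, p1.labels)
        f = unmix_single_trials(
            p1.train, p2.train, p1.labels,
            est.memory_element_, est.preparation_element_, est.a_, est.b_,
        )
        np.testing.assert_array_equal(m1, f[0])
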