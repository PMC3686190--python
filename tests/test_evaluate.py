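"""Splits, AUC, dose-response, thresholds, importance, group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ecominima as em
from ecominima.evaluate import EvalError, dose_response, sample_background


class TestSplit:
    def _occ(self, n):
        return pd.DataFrame({"row": range(n), "col": range(n),
                             "population": 0, "count": 1, "status": "active"})

    def test_seventy_thirty(self):
        cal, evl = em.split(self._occ(10), 0.7, seed=0)
        assert len(cal) == 7 and len(evl) == 3

    def test_disjoint_exhaustive_reproducible(self):
        occ = self._occ(57)
        cal1, evl1 = em.split(occ, 0.7, seed=5)
        cal2, evl2 = em.split(occ, 0.7, seed=5)
        assert cal1.index.equals(cal2.index)
        assert set(cal1.index).isdisjoint(evl1.index)
        assert len(cal1) + len(evl1) == 57

    def test_complementary_fractions_swap_sizes(self):
        occ = self._occ(57)
        cal, evl = em.split(occ, 0.7, seed=1)
        cal2, evl2 = em.split(occ, 0.3, seed=1)
        assert (len(cal), len(evl)) == (len(evl2), len(cal2))

    def test_bad_fraction(self):
        with pytest.raises(EvalError):
            em.split(self._occ(10), 1.0)


class TestAUC:
    def test_perfect_separation(self):
        assert em.auc([1, 1, 1], [0, 0]) == 1.0

    def test_enumerated_pairs(self):
        # pairs: .9>.85, .9>.1, .8<.85, .8>.1 -> 3 wins / 4
        assert em.auc([0.9, 0.8], [0.85, 0.1]) == pytest.approx(0.75)

    def test_identical_distributions_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=4000)
        assert em.auc(s[:2000], s[2000:]) == pytest.approx(0.5, abs=0.03)

    def test_ties_count_half(self):
        assert em.auc([0.5], [0.5]) == 0.5

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(1.0, 1.0, size=60)
        assert em.auc(a, b) + em.auc(b, a) == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(EvalError):
            em.auc([], [1.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=30)
        b = rng.normal(0.5, 1.2, size=40)
        base = em.auc(a, b)
        assert em.auc(np.exp(a), np.exp(b)) == pytest.approx(base)
        assert em.auc(3 * a - 7, 3 * b - 7) == pytest.approx(base)


class TestMedianAndThreshold:
    @pytest.mark.parametrize("scores,expected", [
        ([1.0], 1.0), ([0.0, 1.0], 0.5), ([0.2, 0.8, 0.9], 0.8),
    ])
    def test_median(self, scores, expected):
        assert em.median_hsi(scores) == expected

    def test_threshold_decile_grid(self):
        scores = np.arange(0.1, 1.05, 0.1)
        assert em.hsi_threshold(scores, 0.90) == pytest.approx(0.1)

    def test_threshold_full_coverage_is_minimum(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(size=100)
        assert em.hsi_threshold(s, 1 - 1e-9) == pytest.approx(s.min())

    def test_threshold_constant_scores(self):
        assert em.hsi_threshold([0.4, 0.4, 0.4], 0.9) == 0.4

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1),
           st.floats(0.5, 0.99))
    def test_coverage_guarantee(self, seed, coverage):
        rng = np.random.default_rng(seed)
        s = rng.uniform(size=73)
        t = em.hsi_threshold(s, coverage)
        assert (s >= t).mean() >= coverage


class TestDoseResponse:
    def test_constant_hsi(self):
        rng = np.random.default_rng(3)
        var = rng.uniform(size=(20, 20))
        hsi = np.full((20, 20), 0.5)
        curve = dose_response(var, hsi, lek_values=var.ravel()[:10], n_bins=5)
        nz = ~curve.empty_bins
        assert np.allclose(curve.hsi_mean[nz], 0.5)
        assert np.allclose(curve.hsi_sd[nz], 0.0)

    def test_lek_proportions_sum_to_one(self):
        rng = np.random.default_rng(4)
        var = rng.uniform(size=(20, 20))
        hsi = rng.uniform(size=(20, 20))
        curve = dose_response(var, hsi, lek_values=rng.uniform(size=37),
                              n_bins=8)
        assert curve.lek_proportion.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_bin_concentration(self):
        var = np.linspace(0, 1, 400).reshape(20, 20)
        hsi = np.ones((20, 20)) * 0.3
        curve = dose_response(var, hsi, lek_values=[0.02, 0.03, 0.01], n_bins=10)
        assert curve.lek_proportion[0] == 1.0

    def test_uniform_variable_balanced_bins(self):
        var = np.linspace(0, 1, 100).reshape(10, 10)
        hsi = np.zeros((10, 10)) + 0.5
        curve = dose_response(var, hsi, lek_values=[0.5], n_bins=2)
        assert abs(curve.cell_count[0] - curve.cell_count[1]) <= 1

    def test_degenerate_range_errors(self):
        with pytest.raises(EvalError):
            dose_response(np.ones((5, 5)), np.ones((5, 5)), [1.0], n_bins=4)


class TestImportance:
    def _model(self):
        vecs = np.eye(3)
        return em.PartitionModel(mu=np.zeros(3), sigma=np.ones(3),
                                 eigvals=np.array([1.5, 1.0, 0.5]),
                                 eigvecs=vecs, var_names=["a", "b", "c"],
                                 k_selected=1)

    def test_unit_eigenvector_loading(self):
        m = self._model()
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 3))
        s = X[:, 0]  # scores driven by variable a
        rep = em.variable_importance(m, s, X)
        assert rep.loc[rep["variable"] == "a", "loading_k"].iloc[0] == 1.0
        assert rep.loc[rep["variable"] == "b", "loading_k"].iloc[0] == 0.0

    def test_independent_variable_low_correlation(self):
        m = self._model()
        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 3))
        s = rng.normal(size=400)
        rep = em.variable_importance(m, s, X)
        assert np.all(np.abs(rep["spearman_hsi"]) < 0.2)

    def test_threshold_flags_pattern(self):
        # loadings {0.36, 0.12, ...}: only the first exceeds |0.3|
        vecs = np.zeros((3, 3))
        vecs[:, 0] = [0.36, 0.12, np.sqrt(1 - 0.36 ** 2 - 0.12 ** 2)]
        vecs[:, 1] = [0, 1, 0]
        vecs[:, 2] = [1, 0, 0]
        m = em.PartitionModel(mu=np.zeros(3), sigma=np.ones(3),
                              eigvals=np.array([2.0, 0.6, 0.4]),
                              eigvecs=vecs, var_names=["agri", "soil", "x"],
                              k_selected=1)
        rng = np.random.default_rng(7)
        X = rng.normal(size=(100, 3))
        s = 0.9 * X[:, 0] + 0.9 * X[:, 1] + rng.normal(size=100) * 0.1
        rep = em.variable_importance(m, s, X)
        assert bool(rep.loc[rep["variable"] == "agri", "important"].iloc[0])
        assert not bool(rep.loc[rep["variable"] == "soil", "important"].iloc[0])

    def test_misaligned_lengths(self):
        m = self._model()
        with pytest.raises(EvalError):
            em.variable_importance(m, np.ones(5), np.ones((6, 3)))


class TestGroupSummary:
    def test_constant_group_zero_width_ci(self):
        out = em.group_summary({"g": pd.DataFrame({"v": [2.0, 2.0, 2.0]})})
        row = out.iloc[0]
        assert row["se"] == 0 and row["ci_lo"] == row["ci_hi"] == 2.0

    def test_two_point_closed_form(self):
        out = em.group_summary({"g": pd.DataFrame({"v": [0.0, 2.0]})})
        row = out.iloc[0]
        assert row["mean"] == 1.0 and row["se"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(EvalError):
            em.group_summary({"g": pd.DataFrame({"v": []})})


def test_background_sampler_in_mask():
    mask = np.ones((10, 10), dtype=bool)
    mask[4:6, 4:6] = False
    bg = sample_background(mask, 50, seed=0)
    assert len(bg) == 50
    assert np.all(~mask[bg["row"], bg["col"]])
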