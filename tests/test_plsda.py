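"""NIPALS PLS-DA: fitting, prediction, Venetian-blinds CV, LV choice, VIP."""

import numpy as np
import pytest

from hypertender import (CVSpec, cross_validate, fit, predict, select_n_lv,
                         venetian_folds, vip_scores, vip_select)
from hypertender.evaluate import confusion
from hypertender.preprocess import PreprocessSpec, Step


def toy_separated(rng, n=30, p=8, sep=6.0):
    y = np.where(np.arange(n) % 2 == 0, 1, 2)
    X = rng.standard_normal((n, p))
    X[y == 1, 0] += sep
    return X, y


class TestFitPredict:
    def test_separable_classes_reach_100pct_with_one_lv(self, rng):
        X, y = toy_separated(rng)
        model = fit(X, y, 1)
        _, labels = predict(model, X)
        np.testing.assert_array_equal(labels, y)

    def test_full_lv_model_equals_pseudoinverse_regression(self, rng):
        """With as many LVs as the rank of X, PLS predictions coincide with
        ordinary least squares of the dummy Y on centred X (pinv oracle)."""
        for _ in range(5):
            X = rng.standard_normal((15, 6))
            y = np.asarray([1, 2] * 7 + [1])
            Xc = X - X.mean(axis=0)
            Y = np.stack([[1.0, 0.0] if g == 1 else [0.0, 1.0] for g in y])
            oracle = Xc @ np.linalg.pinv(Xc) @ (Y - Y.mean(0)) + Y.mean(0)
            scores, _ = predict(fit(X, y, 6), X)
            np.testing.assert_allclose(scores, oracle, atol=1e-8)

    def test_joint_row_permutation_leaves_model_unchanged(self, rng):
        X, y = toy_separated(rng, n=20)
        perm = rng.permutation(20)
        m1, m2 = fit(X, y, 3), fit(X[perm], y[perm], 3)
        np.testing.assert_allclose(m1.B, m2.B, atol=1e-10)
        np.testing.assert_allclose(m1.W, m2.W, atol=1e-10)

    def test_class_scores_sum_to_one(self, rng):
        X, y = toy_separated(rng)
        scores, _ = predict(fit(X, y, 3), rng.standard_normal((12, 8)))
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-10)

    def test_duplicated_rows_score_identically(self, rng):
        X, y = toy_separated(rng)
        model = fit(X, y, 2)
        row = rng.standard_normal(8)
        scores, _ = predict(model, np.stack([row, row]))
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_score_vectors_are_orthogonal(self, rng):
        X, y = toy_separated(rng, n=40, p=12)
        Xc = X - X.mean(0)
        model = fit(X, y, 5)
        T = Xc @ model.W @ np.linalg.inv(model.P.T @ model.W)
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_explained_x_variance_nondecreasing_and_below_100(self, rng):
        X, y = toy_separated(rng, n=40, p=12)
        model = fit(X, y, 6)
        ev = model.explained_x_variance
        assert np.all(np.diff(ev) >= -1e-10)
        assert ev[-1] <= 100.0 + 1e-9

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            fit(X, np.ones(10, dtype=int), 2)

    def test_n_lv_beyond_rank_rejected(self, rng):
        X, y = toy_separated(rng, n=10, p=4)
        with pytest.raises(ValueError):
            fit(X, y, 5)

    def test_band_mismatch_on_predict(self, rng):
        X, y = toy_separated(rng)
        with pytest.raises(ValueError):
            predict(fit(X, y, 2), rng.standard_normal((3, 5)))


class TestVenetianBlinds:
    def test_units_assigned_modulo_in_canonical_order(self):
        units = np.array(["s3", "s1", "s2", "s4", "s1", "s3"])
        folds = venetian_folds(units, 2)
        # sorted units s1 s2 s3 s4 -> folds 0 1 0 1
        np.testing.assert_array_equal(folds[0],
                                      [False, True, False, False, True, False]
                                      | np.array([True, False, False, False,
                                                  False, True]))
        np.testing.assert_array_equal(folds[1],
                                      [False, False, True, True, False, False])

    def test_fold_sizes_differ_by_at_most_one_unit(self):
        units = np.arange(23)
        folds = venetian_folds(units, 10)
        sizes = [f.sum() for f in folds]
        assert max(sizes) - min(sizes) <= 1

    def test_splits_equal_units_gives_leave_one_out(self):
        units = np.array([0, 0, 1, 2, 2, 3])
        folds = venetian_folds(units, 4)
        for k, f in enumerate(folds):
            assert set(units[f]) == {k}

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            venetian_folds(np.array([1, 2, 3]), 4)


class TestCrossValidate:
    def test_separable_data_cross_validates_cleanly(self, rng):
        X, y = toy_separated(rng, n=60, p=10)
        units = np.repeat(np.arange(12), 5)
        summaries = cross_validate(X, y, units, CVSpec(n_splits=4, max_lv=3))
        assert summaries[0].mean_percent_cc == 100.0

    def test_preprocessing_refit_per_fold(self, rng):
        X, y = toy_separated(rng, n=60, p=30)
        units = np.repeat(np.arange(12), 5)
        chain = PreprocessSpec((Step("mean_center"),))
        summaries = cross_validate(X, y, units, CVSpec(n_splits=4, max_lv=3),
                                   preprocess=chain)
        assert len(summaries) == 3

    def test_chance_level_on_pure_noise(self, rng):
        """Pixel blocks with no class signal cross-validate near 50% CC."""
        n = 12000
        X = rng.standard_normal((n, 20))
        y = np.where(np.arange(n) % 2 == 0, 1, 2)
        units = np.repeat(np.arange(40), n // 40)
        summaries = cross_validate(X, y, units, CVSpec(n_splits=10, max_lv=5))
        for s in summaries:
            assert 45.0 <= s.mean_percent_cc <= 55.0


class TestSelectNLv:
    class FakeSummary:
        def __init__(self, cc):
            self.mean_percent_cc = cc

    def test_first_lv_on_the_plateau_is_chosen(self):
        ccs = [60, 70, 80, 89.5, 90, 90.2]
        n = select_n_lv([self.FakeSummary(c) for c in ccs])
        assert n == 4  # 89.5 is within 1 point of the 90.2 max

    def test_single_candidate_returned(self):
        assert select_n_lv([self.FakeSummary(75.0)]) == 1

    def test_recovers_three_informative_directions(self, rng):
        """Class signal spread over three axes whose first two also carry
        large uninformative variance: one or two LVs cannot reach the
        accuracy plateau, so the parsimony rule picks at least three."""
        n, p = 1000, 30
        y = np.where(np.arange(n) % 2 == 0, 1, 2)
        sign = np.where(y == 1, 1.0, -1.0)
        X = rng.standard_normal((n, p)) * 0.5
        X[:, 0] += rng.standard_normal(n) * 8.0 + sign * 2.0
        X[:, 1] += rng.standard_normal(n) * 3.0 + sign * 1.0
        X[:, 2] += sign * 0.5
        units = np.repeat(np.arange(20), n // 20)
        summaries = cross_validate(X, y, units, CVSpec(n_splits=10, max_lv=8))
        assert select_n_lv(summaries) >= 3


class TestVIP:
    def test_single_band_model_has_vip_one(self, rng):
        y = np.asarray([1, 2] * 10)
        X = rng.standard_normal((20, 1)) + np.where(y == 1, 2.0, 0.0)[:, None]
        model = fit(X, y, 1)
        np.testing.assert_allclose(vip_scores(model), [1.0])

    def test_mean_squared_vip_is_one(self, rng):
        X, y = toy_separated(rng, n=40, p=12)
        vip = vip_scores(fit(X, y, 4))
        assert (vip ** 2).mean() == pytest.approx(1.0, abs=1e-10)
        assert (vip ** 2).sum() == pytest.approx(12.0, abs=1e-8)

    def test_signal_bands_dominate_vip(self, rng):
        n, p = 400, 80
        y = np.where(np.arange(n) % 2 == 0, 1, 2)
        X = rng.standard_normal((n, p))
        X[y == 1, 40:61] += 1.5  # signal confined to bands 40-60
        model = fit(X, y, 3)
        vip = vip_scores(model)
        selected = np.nonzero(vip > 1.0)[0]
        assert len(selected) > 0
        assert np.all((selected >= 40) & (selected <= 60))

    def test_vip_select_returns_wavelengths_above_threshold(self):
        wl = np.array([1000.0, 1100.0, 1200.0])
        np.testing.assert_array_equal(
            vip_select(np.array([0.5, 1.2, 2.0]), wl), [1100.0, 1200.0])
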