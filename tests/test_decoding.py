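"""Binning, pseudo-trials, shrinkage LDA, AUC, forward models, (cross-)decoding."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhi_mvpa import (
    DecodingConfig,
    bin_epochs,
    compute_auc,
    cross_classify,
    decode_timecourse,
    fit_lda,
    forward_model,
    make_pseudo_trials,
)

from conftest import make_epochs


def brute_force_auc(scores, labels):
    """Pairwise enumeration oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    pos, neg = scores[labels == classes[1]], scores[labels == classes[0]]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


class TestBinning:
    def test_bin_count_matches_formula(self):
        ep = make_epochs(n_samples=161, fs=200.0)
        feats, centers = bin_epochs(ep, 0.06, 0.01)
        assert feats.shape[0] == (161 - 12) // 2 + 1 == 75
        assert centers.size == 75

    def test_bin_covers_center_plus_minus_half_width(self):
        # a reported effect time c labels the bin covering [c-0.03, c+0.03] s
        ep = make_epochs(n_samples=161, fs=200.0)
        _, centers = bin_epochs(ep, 0.06, 0.01)
        for b in (0, 37, 74):
            start = ep.times[0] + b * 0.01
            assert start == pytest.approx(centers[b] - 0.03)
            assert start + 0.06 == pytest.approx(centers[b] + 0.03)
        assert np.all(np.diff(centers) > 0)

    def test_constant_epoch_gives_constant_features(self):
        ep = make_epochs(data=np.full((3, 2, 161), 4.25))
        feats, _ = bin_epochs(ep)
        np.testing.assert_allclose(feats, 4.25)

    def test_feature_is_within_bin_mean(self):
        ep = make_epochs(n_epochs=2, n_channels=3)
        feats, _ = bin_epochs(ep, 0.06, 0.01)
        np.testing.assert_allclose(feats[5, 1, 2], ep.data[1, 2, 10:23].mean())

    def test_off_grid_step_snaps_with_warning(self):
        ep = make_epochs(fs=200.0)
        with pytest.warns(UserWarning, match="snapped"):
            bin_epochs(ep, 0.06, 0.012)


class TestPseudoTrials:
    def test_eight_epochs_two_pseudo_trials(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((8, 3))
        out, labels = make_pseudo_trials(X, np.zeros(8), 4, rng)
        assert out.shape == (2, 3)
        # each pseudo-trial is the mean of its members; together they use all 8
        np.testing.assert_allclose(out.mean(axis=0), X.mean(axis=0))

    def test_leftovers_discarded(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((23, 2))
        out, _ = make_pseudo_trials(X, np.zeros(23), 4, rng)
        assert out.shape[0] == 5

    def test_group_size_one_is_identity(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((6, 2))
        out, _ = make_pseudo_trials(X, np.zeros(6), 1, rng)
        np.testing.assert_allclose(np.sort(out, axis=0), np.sort(X, axis=0))

    def test_grouping_is_within_class(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([np.zeros((8, 2)), np.ones((8, 2))])
        y = np.repeat([0, 1], 8)
        out, labels = make_pseudo_trials(X, y, 4, rng)
        np.testing.assert_allclose(out[labels == 0], 0.0)
        np.testing.assert_allclose(out[labels == 1], 1.0)

    def test_too_small_class_errors(self):
        with pytest.raises(ValueError, match="fewer than the"):
            make_pseudo_trials(np.zeros((3, 2)), np.zeros(3), 4, np.random.default_rng(0))


class TestLda:
    def test_identity_covariance_weights_along_mean_difference(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.standard_normal((200, 2)),
                            rng.standard_normal((200, 2)) + [2, 0]])
        y = np.repeat([0, 1], 200)
        m = fit_lda(X, y, reg_lambda=0.0)
        assert abs(m.weights[1] / m.weights[0]) < 0.1

    def test_full_shrinkage_weights_proportional_to_mean_difference(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 5)) @ rng.standard_normal((5, 5))
        y = np.repeat([0, 1], 20)
        X[y == 1] += rng.standard_normal(5)
        m = fit_lda(X, y, reg_lambda=1.0)
        diff = X[y == 1].mean(0) - X[y == 0].mean(0)
        cos = m.weights @ diff / np.linalg.norm(m.weights) / np.linalg.norm(diff)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_weights_match_independent_solve(self):
        # oracle: assemble the shrunk covariance from np.cov and solve directly
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = 5
            A = rng.standard_normal((d, d))
            X0 = rng.standard_normal((30, d)) @ A
            X1 = rng.standard_normal((34, d)) @ A + rng.standard_normal(d)
            X = np.concatenate([X0, X1])
            y = np.repeat([0, 1], [30, 34])
            m = fit_lda(X, y, reg_lambda=0.1)
            cov = ((np.cov(X0.T) * 29 + np.cov(X1.T) * 33) / 62)
            shrunk = 0.9 * cov + 0.1 * np.trace(cov) / d * np.eye(d)
            expected = np.linalg.solve(shrunk, X1.mean(0) - X0.mean(0))
            np.testing.assert_allclose(m.weights, expected, atol=1e-10)

    def test_shrinkage_monotonically_aligns_with_mean_difference(self):
        rng = np.random.default_rng(3)
        A = rng.standard_normal((6, 6))
        X = np.concatenate([rng.standard_normal((25, 6)) @ A,
                            rng.standard_normal((25, 6)) @ A + 1.0])
        y = np.repeat([0, 1], 25)
        diff = X[y == 1].mean(0) - X[y == 0].mean(0)
        diff /= np.linalg.norm(diff)
        angles = []
        for lam in (0.0, 0.3, 0.7, 1.0):
            w = fit_lda(X, y, lam).weights
            angles.append(np.arccos(np.clip(w @ diff / np.linalg.norm(w), -1, 1)))
        assert angles == sorted(angles, reverse=True)
        assert angles[-1] == pytest.approx(0.0, abs=1e-8)

    def test_singular_covariance_without_shrinkage_errors(self):
        X = np.zeros((10, 3))
        X[:, 0] = np.arange(10)  # two dead dimensions
        y = np.repeat([0, 1], 5)
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            fit_lda(X, y, reg_lambda=0.0)

    def test_batched_fit_matches_scalar_fit(self):
        from rhi_mvpa.decoding import _fit_lda_batch

        rng = np.random.default_rng(5)
        X = rng.standard_normal((7, 24, 6))
        y = np.repeat([0, 1], 12)
        W, bias = _fit_lda_batch(X, y, 0.1)
        for b in range(7):
            m = fit_lda(X[b], y, 0.1)
            np.testing.assert_allclose(W[b], m.weights, atol=1e-12)
            assert bias[b] == pytest.approx(m.bias, abs=1e-12)

    def test_batched_forward_model_matches_scalar(self):
        from rhi_mvpa.decoding import _fit_lda_batch, _forward_model_batch

        rng = np.random.default_rng(6)
        X = rng.standard_normal((4, 30, 5))
        y = np.repeat([0, 1], 15)
        X[:, y == 1, :] += 0.5
        W, bias = _fit_lda_batch(X, y, 0.2)
        fwd = _forward_model_batch(X, W)
        for b in range(4):
            m = fit_lda(X[b], y, 0.2)
            np.testing.assert_allclose(fwd[:, b], forward_model(m, X[b]), atol=1e-12)

    def test_decision_values_monotone_in_class1_direction(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.standard_normal((50, 3)),
                            rng.standard_normal((50, 3)) + 2])
        y = np.repeat([0, 1], 50)
        m = fit_lda(X, y)
        assert m.decision_values(X)[y == 1].mean() > m.decision_values(X)[y == 0].mean()


class TestAuc:
    def test_perfect_separation(self):
        assert compute_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0

    def test_all_ties_is_chance(self):
        assert compute_auc(np.ones(10), np.repeat([0, 1], 5)) == 0.5

    def test_enumerated_example(self):
        # pairs: (2>1), (2<3), (4>1), (4>3) -> 3 of 4 concordant
        assert compute_auc([1, 2, 3, 4], [0, 1, 0, 1]) == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            compute_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_pairwise_enumeration(self, data):
        n = data.draw(st.integers(4, 40))
        scores = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
        labels = np.zeros(n, int)
        labels[: n // 2] = 1
        assert compute_auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        scores = rng.integers(0, 4, 60).astype(float)
        labels = rng.integers(0, 2, 60)
        if len(np.unique(labels)) == 2:
            assert compute_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12)


class TestForwardModel:
    def test_channel_equal_to_discriminant_scores_one(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 3))
        m = fit_lda(np.concatenate([X, X + [1, 0, 0]]), np.repeat([0, 1], 100))
        Xa = np.concatenate([X, X + [1, 0, 0]])
        s = Xa @ m.weights
        Xa2 = np.column_stack([Xa, s])
        m2 = dataclasses.replace(m, weights=np.append(m.weights, 0.0))
        fm = forward_model(m2, Xa2)
        assert fm[-1] == pytest.approx(1.0)

    def test_rank_one_data_recovers_topography(self):
        rng = np.random.default_rng(1)
        a = np.array([3.0, -1.0, 2.0, 0.5])
        s = rng.standard_normal(200)
        X = np.outer(s, a)
        m = fit_lda(np.concatenate([X, X + 0.01 * a]), np.repeat([0, 1], 200), 0.5)
        fm = forward_model(m, X)
        # noiseless rank-one data: every channel correlates +/-1 with the
        # discriminant, signs matching the pattern
        np.testing.assert_allclose(np.abs(fm), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.sign(fm), np.sign(a))

    def test_values_bounded_and_dead_channel_zero(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((50, 4))
        X[:, 3] = 1.0
        m = fit_lda(np.concatenate([X, X + 1]), np.repeat([0, 1], 50))
        with pytest.warns(UserWarning, match="zero-variance"):
            fm = forward_model(m, X)
        assert np.all(np.abs(fm) <= 1.0) and fm[3] == 0.0


def two_condition_epochs(n=80, n_ch=8, seed=0, effect=0.0, window=(0.08, 0.30)):
    """Noise epochs for two conditions; condition A optionally carries a
    pattern inside the window."""
    rng = np.random.default_rng(seed)
    pattern = rng.standard_normal(n_ch)
    pattern /= np.linalg.norm(pattern)
    times = (np.arange(161) - 80) / 200.0
    bump = np.where((times >= window[0]) & (times <= window[1]), 1.0, 0.0)
    a = rng.standard_normal((n, n_ch, 161))
    b = rng.standard_normal((n, n_ch, 161))
    a += effect * np.einsum("c,s->cs", pattern, bump)
    ds_a = make_epochs(data=a, condition="IllusionNext")
    ds_b = make_epochs(data=b, condition="IncongruentNext")
    return ds_a, ds_b, pattern


class TestDecodeTimecourse:
    CFG = DecodingConfig(n_repeats=3, bin_step=0.02, rng_seed=5)

    def test_same_distribution_stays_near_chance(self):
        ds_a, ds_b, _ = two_condition_epochs(seed=3)
        curve = decode_timecourse(ds_a, ds_b, self.CFG)
        assert 0.4 < curve.auc.mean() < 0.6
        assert np.all((curve.auc >= 0) & (curve.auc <= 1))

    def test_injected_effect_peaks_inside_window(self):
        ds_a, ds_b, _ = two_condition_epochs(seed=4, effect=2.0)
        curve = decode_timecourse(ds_a, ds_b, self.CFG)
        peak = curve.bin_centers[np.argmax(curve.auc)]
        # bins overlapping the window edge also carry signal: allow half a bin
        assert 0.05 <= peak <= 0.33
        assert curve.auc.max() > 0.8

    def test_class_swap_symmetry(self):
        # AUC is symmetric under swapping the two conditions; with fresh
        # resampling draws the two curves agree statistically
        ds_a, ds_b, _ = two_condition_epochs(seed=5, effect=1.0)
        cfg = dataclasses.replace(self.CFG, n_repeats=10)
        c1 = decode_timecourse(ds_a, ds_b, cfg)
        c2 = decode_timecourse(ds_b, ds_a, cfg)
        assert c1.auc.mean() == pytest.approx(c2.auc.mean(), abs=0.02)
        w = (c1.bin_centers >= 0.08) & (c1.bin_centers <= 0.30)
        assert c1.auc[w].mean() == pytest.approx(c2.auc[w].mean(), abs=0.05)

    def test_reproducible_given_seed(self):
        ds_a, ds_b, _ = two_condition_epochs(seed=6)
        c1 = decode_timecourse(ds_a, ds_b, self.CFG)
        c2 = decode_timecourse(ds_a, ds_b, self.CFG)
        np.testing.assert_array_equal(c1.auc, c2.auc)
        np.testing.assert_array_equal(c1.forward_model, c2.forward_model)

    def test_too_few_pseudo_trials_errors(self):
        ds_a, ds_b, _ = two_condition_epochs(n=20)
        with pytest.raises(ValueError, match="pseudo-trials"):
            decode_timecourse(ds_a, ds_b, DecodingConfig(n_folds=6))

    def test_forward_model_recovers_pattern_at_high_snr(self):
        ds_a, ds_b, pattern = two_condition_epochs(n=120, seed=7, effect=3.0)
        curve = decode_timecourse(ds_a, ds_b, self.CFG)
        b = int(np.argmax(curve.auc))
        r = np.corrcoef(curve.forward_model[:, b], pattern)[0, 1]
        assert abs(r) > 0.9


class TestCrossClassify:
    CFG = DecodingConfig(n_repeats=3, bin_step=0.02, rng_seed=8)

    def test_shared_pattern_generalizes(self):
        rng = np.random.default_rng(0)
        pattern = rng.standard_normal(8)
        pattern /= np.linalg.norm(pattern)
        times = (np.arange(161) - 80) / 200.0
        bump = ((times >= 0.1) & (times <= 0.3)).astype(float)
        sig = 2.0 * np.einsum("c,s->cs", pattern, bump)
        ill = make_epochs(data=rng.standard_normal((120, 8, 161)) + sig,
                          condition="Illusion")
        inc = make_epochs(data=rng.standard_normal((120, 8, 161)),
                          condition="Incongruent")
        real = make_epochs(data=rng.standard_normal((120, 8, 161)),
                           condition="Real")
        curve = cross_classify(ill, inc, ill, real, self.CFG)
        w = (curve.bin_centers >= 0.1) & (curve.bin_centers <= 0.3)
        assert curve.auc[w].mean() > 0.7

    def test_same_pair_reduces_to_ordinary_decoding(self):
        rng = np.random.default_rng(1)
        ds_a, ds_b, _ = two_condition_epochs(n=120, seed=9, effect=1.5)
        cross = cross_classify(ds_a, ds_b, ds_a, ds_b, self.CFG)
        plain = decode_timecourse(ds_a, ds_b, self.CFG)
        w = (cross.bin_centers >= 0.08) & (cross.bin_centers <= 0.30)
        assert cross.auc[w].mean() == pytest.approx(plain.auc[w].mean(), abs=0.1)
        assert cross.auc[~w].mean() == pytest.approx(0.5, abs=0.05)

    def test_overlapping_contrast_sides_error(self):
        ds_a, ds_b, _ = two_condition_epochs()
        with pytest.raises(ValueError, match="disjoint"):
            cross_classify(ds_a, ds_a, ds_a, ds_b, self.CFG)
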