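"""Decoding, dimensionality, PCA and dF/F-lick correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import special_ortho_group

from mlipop import behavior, decode
from mlipop import dff as dffm
from mlipop.config import PeriodWindows


def two_clouds(rng, n_per=20, d=5, sep=6.0, sd=1.0):
    a = rng.normal(0, sd, size=(n_per, d))
    b = rng.normal(0, sd, size=(n_per, d)) + sep / np.sqrt(d)
    X = np.vstack([a, b])
    y = np.array(["A"] * n_per + ["B"] * n_per)
    return X, y


def brute_force_fisher_predictions(X, y):
    """Independent Fisher-rule oracle: explicit class means, elementwise
    pooled covariance, pinv whitening, nearest class mean (equal priors)."""
    preds = []
    classes = sorted(set(y))
    for i in range(len(X)):
        Xtr = np.delete(X, i, axis=0)
        ytr = np.delete(y, i)
        mus = {}
        n_feat = X.shape[1]
        S = np.zeros((n_feat, n_feat))
        for c in classes:
            pts = Xtr[ytr == c]
            mu = np.array([pts[:, j].sum() / len(pts) for j in range(n_feat)])
            mus[c] = mu
            for p in pts:
                diff = p - mu
                for a in range(n_feat):
                    for b in range(n_feat):
                        S[a, b] += diff[a] * diff[b]
        S /= max(len(Xtr) - len(classes), 1)
        Sinv = np.linalg.pinv(S)
        x = X[i]
        scores = {c: -0.5 * (x - mus[c]) @ Sinv @ (x - mus[c])
                  for c in classes}
        preds.append(max(scores, key=scores.get))
    return np.array(preds)


class TestLooLda:
    def test_separated_clouds_perfect(self, rng):
        X, y = two_clouds(rng, sep=20.0)
        assert decode.loo_lda_accuracy(X, y) == 1.0

    def test_chance_level_overlapping(self):
        """Same-distribution classes decode at chance (binomial band)."""
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, size=(100, 5))
            y = np.array(["A", "B"] * 50)
            accs.append(decode.loo_lda_accuracy(X, y))
        band = 2 * np.sqrt(0.25 / 100)       # ~95% binomial band
        assert abs(np.mean(accs) - 0.5) < band

    def test_univariate_gaussian_oracle(self):
        """1-ROI decoding approaches the Phi(d/2) Bayes accuracy."""
        d = 3.0
        accs = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            X = np.concatenate([r.normal(0, 1, 60),
                                r.normal(d, 1, 60)])[:, None]
            y = np.array(["A"] * 60 + ["B"] * 60)
            accs.append(decode.loo_lda_accuracy(X, y))
        expected = stats.norm.cdf(d / 2)     # ~0.933
        assert abs(np.mean(accs) - expected) < 0.05
        assert np.mean(accs) > 0.8

    def test_matches_brute_force_fisher_oracle(self):
        """LOO predictions equal an exhaustive Fisher-rule oracle on toy sets."""
        for seed in range(12):
            r = np.random.default_rng(seed)
            X, y = two_clouds(r, n_per=4, d=2, sep=2.0)
            oracle = brute_force_fisher_predictions(X, y)
            acc_oracle = np.mean(oracle == y)
            assert decode.loo_lda_accuracy(X, y) == pytest.approx(acc_oracle)

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(st.floats(min_value=0.1, max_value=50.0),
           st.floats(min_value=-10.0, max_value=10.0))
    def test_affine_invariance(self, scale, shift):
        """Rescaling/shifting one ROI column leaves accuracy unchanged."""
        r = np.random.default_rng(7)
        X, y = two_clouds(r, n_per=10, d=3, sep=3.0)
        base = decode.loo_lda_accuracy(X, y)
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] * scale + shift
        assert decode.loo_lda_accuracy(X2, y) == pytest.approx(base)

    def test_matches_sklearn_lda(self):
        """Held-out predictions agree with an off-the-shelf LDA on
        well-conditioned data (independent library cross-check)."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        for seed in range(5):
            r = np.random.default_rng(seed)
            X, y = two_clouds(r, n_per=15, d=4, sep=3.0)
            correct = 0
            for i in range(len(X)):
                mask = np.ones(len(X), dtype=bool)
                mask[i] = False
                clf = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
                clf.fit(X[mask], y[mask])
                correct += clf.predict(X[i:i + 1])[0] == y[i]
            assert decode.loo_lda_accuracy(X, y) == pytest.approx(
                correct / len(X))

    def test_small_class_raises(self):
        X = np.zeros((3, 2))
        with pytest.raises(ValueError):
            decode.loo_lda_accuracy(X, np.array(["A", "A", "B"]))


class TestDecodingTimecourse:
    def make_tensor(self, values, rate=5.3):
        return dffm.TrialTensor(values=values,
                                t_rel=np.arange(values.shape[2]) / rate,
                                alignment="odor_on",
                                trial_indices=np.arange(values.shape[0]),
                                imaging_rate=rate)

    def test_null_accuracy_inside_band(self):
        """Labels independent of data: accuracy stays inside the shuffled
        band at the vast majority of timepoints (the band estimates the
        null accuracy distribution, ~95% pointwise coverage)."""
        r = np.random.default_rng(3)
        values = r.normal(0, 1, size=(40, 8, 12))
        y = np.array(["A", "B"] * 20)
        res = decode.decoding_timecourse(self.make_tensor(values), y,
                                         n_shuffles=20, seed=0)
        lo, hi = res.shuffled_ci
        inside = np.mean((res.accuracy >= lo - 1e-9)
                         & (res.accuracy <= hi + 1e-9))
        assert inside >= 0.8

    def test_signal_exits_band_post_odor_only(self):
        r = np.random.default_rng(4)
        values = r.normal(0, 1, size=(40, 8, 12))
        y = np.array(["A", "B"] * 20)
        values[np.array(y) == "B", :, 6:] += 3.0     # signal after frame 6
        res = decode.decoding_timecourse(self.make_tensor(values), y,
                                         n_shuffles=20, seed=0)
        hi = res.shuffled_ci[1]
        assert np.all(res.accuracy[7:] > hi[7:])
        assert np.mean(res.accuracy[:6] > hi[:6]) < 0.5

    def test_no_shuffles_flagged(self):
        r = np.random.default_rng(5)
        values = r.normal(0, 1, size=(12, 4, 5))
        y = np.array(["A", "B"] * 6)
        res = decode.decoding_timecourse(self.make_tensor(values), y,
                                         n_shuffles=0)
        assert res.shuffled_ci is None


class TestSubsampleDecoding:
    def test_full_size_equals_full_accuracy(self, rng):
        X, y = two_clouds(rng, n_per=15, d=6, sep=4.0)
        curve = decode.subsample_decoding(X, y, sizes=(6,), n_draws=50)
        assert curve.subset_sizes.tolist() == [6]
        assert curve.accuracy_mean[0] == pytest.approx(
            decode.loo_lda_accuracy(X, y))

    def test_redundant_ensemble_single_roi_close_to_full(self):
        """Rank-one signal: one ROI decodes nearly as well as the ensemble."""
        r = np.random.default_rng(6)
        n_per, d = 25, 12
        signal = np.concatenate([np.zeros(n_per), np.ones(n_per) * 4.0])
        X = signal[:, None] + r.normal(0, 0.6, size=(2 * n_per, d))
        y = np.array(["A"] * n_per + ["B"] * n_per)
        curve = decode.subsample_decoding(X, y, sizes=(1, d), n_draws=30)
        full = curve.accuracy_mean[curve.subset_sizes == d][0]
        single = curve.accuracy_mean[curve.subset_sizes == 1][0]
        assert full - single < 0.15

    def test_pure_noise_all_chance(self):
        r = np.random.default_rng(8)
        X = r.normal(0, 1, size=(60, 10))
        y = np.array(["A", "B"] * 30)
        curve = decode.subsample_decoding(X, y, sizes=(1, 5, 10), n_draws=20)
        assert np.all(np.abs(curve.accuracy_mean - 0.5) < 0.15)

    def test_oversized_subset_skipped(self, rng):
        X, y = two_clouds(rng, n_per=10, d=4)
        curve = decode.subsample_decoding(X, y, sizes=(2, 99), n_draws=5)
        assert curve.subset_sizes.tolist() == [2]


class TestDimensionality:
    def test_iid_equal_variance_equals_m(self):
        r = np.random.default_rng(0)
        M = 6
        X = r.normal(0, 1, size=(20000, M))
        assert decode.dimensionality(X) == pytest.approx(M, abs=0.15)

    def test_rank_one_equals_one(self):
        r = np.random.default_rng(1)
        z = r.normal(0, 1, size=500)
        X = np.outer(z, np.array([1.0, -2.0, 0.5]))
        assert decode.dimensionality(X) == pytest.approx(1.0, abs=1e-9)

    def test_known_spectrum(self):
        """Eigenvalues {2,1,1} give (2+1+1)^2/(4+1+1) = 16/6."""
        r = np.random.default_rng(2)
        n = 200000
        X = r.normal(0, 1, size=(n, 3)) * np.sqrt([2.0, 1.0, 1.0])
        assert decode.dimensionality(X) == pytest.approx(16 / 6, abs=0.02)

    def test_rotation_invariance(self):
        r = np.random.default_rng(3)
        X = r.normal(0, 1, size=(300, 5)) * np.array([2, 1, 1, 0.5, 0.1])
        Q = special_ortho_group.rvs(5, random_state=4)
        assert decode.dimensionality(X @ Q) == pytest.approx(
            decode.dimensionality(X), rel=1e-9)

    def test_adding_independent_roi_increases_dim(self):
        r = np.random.default_rng(5)
        n, M = 100000, 4
        X = r.normal(0, 1, size=(n, M))
        X2 = np.column_stack([X, r.normal(0, 1, size=n)])
        d1, d2 = decode.dimensionality(X), decode.dimensionality(X2)
        assert d2 - d1 == pytest.approx(1.0, abs=0.2)

    def test_zero_covariance_raises(self):
        with pytest.raises(ValueError):
            decode.dimensionality(np.ones((10, 3)))


class TestPca:
    def test_line_data_pc2_zero(self):
        r = np.random.default_rng(0)
        z = r.normal(0, 1, 50)
        X = np.outer(z, [1.0, 2.0, 3.0])
        scores = decode.pca_projection(X)
        assert np.allclose(scores[:, 1], 0, atol=1e-8)

    def test_separated_classes_separate_in_pc_space(self, rng):
        X, y = two_clouds(rng, n_per=30, d=8, sep=10.0)
        scores = decode.pca_projection(X)
        da = scores[:30].mean(axis=0)
        db = scores[30:].mean(axis=0)
        assert np.linalg.norm(da - db) > 3.0

    def test_rotation_changes_scores_only_by_sign(self):
        r = np.random.default_rng(1)
        X = r.normal(0, 1, size=(40, 5)) * np.array([3, 2, 1, 0.5, 0.2])
        Q = special_ortho_group.rvs(5, random_state=2)
        s1 = decode.pca_projection(X)
        s2 = decode.pca_projection(X @ Q)
        for j in range(2):
            assert (np.allclose(s1[:, j], s2[:, j], atol=1e-8)
                    or np.allclose(s1[:, j], -s2[:, j], atol=1e-8))

    def test_constant_data_raises(self):
        with pytest.raises(ValueError):
            decode.pca_projection(np.ones((10, 4)))


class TestDffLickCorrelation:
    def test_perfect_linear_relation(self, proficient_session, windows):
        s = proficient_session
        n = int(s.duration_s * s.imaging_rate)
        ft = np.arange(n) / s.imaging_rate
        lick = behavior.lick_rate(s.lick_times, ft).rate
        mean_dff = 2.0 * lick + 1.0
        res = decode.dff_lick_correlation(mean_dff, lick, s, windows)
        for period, (rho, p) in res.items():
            assert rho == pytest.approx(1.0, abs=1e-9)

    def test_independent_series_near_zero(self, proficient_session, windows):
        s = proficient_session
        n = int(s.duration_s * s.imaging_rate)
        r = np.random.default_rng(0)
        res = decode.dff_lick_correlation(r.normal(0, 1, n),
                                          r.normal(0, 1, n), s, windows)
        for period, (rho, p) in res.items():
            assert abs(rho) < 0.1

    def test_generator_coupling_recovered(self, proficient_session,
                                          proficient_dff, windows):
        """Reinforcement-window rho recovers the configured 0.73 coupling."""
        s = proficient_session
        ft = np.arange(proficient_dff.shape[0]) / s.imaging_rate
        lick = behavior.lick_rate(s.lick_times, ft).rate
        res = decode.dff_lick_correlation(proficient_dff.mean(axis=1), lick,
                                          s, windows)
        rho, p = res["reinforcement"]
        assert rho == pytest.approx(0.73, abs=0.1)
        assert p < 0.001

    def test_derivative_mode_runs(self, proficient_session, proficient_dff,
                                  windows):
        s = proficient_session
        ft = np.arange(proficient_dff.shape[0]) / s.imaging_rate
        lick = behavior.lick_rate(s.lick_times, ft).rate
        res = decode.dff_lick_correlation(proficient_dff.mean(axis=1), lick,
                                          s, windows, use_derivatives=True)
        assert set(res) == {"pre_odorant", "odorant", "reinforcement"}
        assert all(np.isfinite(v[0]) for v in res.values())
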