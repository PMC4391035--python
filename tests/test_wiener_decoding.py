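"""Decoder correctness: OLS oracle equivalence, recovery, CV mechanics,
channel ranking, lag contributions, peak fitting, significance."""

import numpy as np
import pytest

import graspdecode as gd
from graspdecode.wiener_decoding import (
    _double_exp,
    _fit_double_exponential,
)

from _util import make_trialset


def _pinv_oracle(trials, y):
    """Independent least-squares route: SVD pseudoinverse of the design."""
    x = trials.design_matrix()
    xd = np.column_stack([x, np.ones(x.shape[0])])
    return np.linalg.pinv(xd) @ y


class TestFitOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_fit_matches_pseudoinverse_solve(self, seed):
        """Random instances up to 5 channels x 3 lags: coefficients agree
        with the explicit pseudoinverse solution to 1e-8."""
        rng = np.random.default_rng(seed)
        n_ch = int(rng.integers(2, 6))
        n_lag = int(rng.integers(1, 4))
        ts = make_trialset(n_trials=3, t_len=60, n_channels=n_ch,
                           n_lags=n_lag, rng=rng)
        model = gd.fit_wiener(ts, outputs="joints")
        beta = _pinv_oracle(ts, ts.stacked_velocities())
        got = np.vstack([model.coef_flat, model.intercepts])
        np.testing.assert_allclose(got, beta, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_normal_equations_satisfied(self, seed):
        rng = np.random.default_rng(seed)
        ts = make_trialset(n_trials=2, t_len=80, n_channels=4, n_lags=2,
                           rng=rng)
        model = gd.fit_wiener(ts, outputs="joints")
        x = ts.design_matrix()
        resid = ts.stacked_velocities() - (x @ model.coef_flat
                                           + model.intercepts)
        np.testing.assert_allclose(x.T @ resid, 0.0, atol=1e-8)

    def test_exact_recovery_of_generating_coefficients(self, rng):
        """Noise-free linear data: fitted beta equals generating beta."""
        n_ch, n_lag, t = 4, 3, 400
        eeg = rng.standard_normal((t, n_ch, n_lag))
        beta = rng.standard_normal((n_ch * n_lag, 15))
        b0 = rng.standard_normal(15)
        vel = eeg.reshape(t, -1) @ beta + b0
        ts = make_trialset([eeg], [vel], ["can"], rng=rng)
        model = gd.fit_wiener(ts, outputs="joints")
        np.testing.assert_allclose(model.coef_flat, beta, atol=1e-8)
        np.testing.assert_allclose(model.intercepts, b0, atol=1e-8)

    def test_zero_eeg_gives_mean_intercept_and_zero_coefficients(self, rng,
                                                                 caplog):
        vel = rng.standard_normal((100, 15))
        ts = make_trialset([np.zeros((100, 2, 3))], [vel], ["can"], rng=rng)
        with caplog.at_level("WARNING"):
            model = gd.fit_wiener(ts, outputs="joints")
        assert "rank-deficient" in caplog.text
        np.testing.assert_allclose(model.coef_flat, 0.0, atol=1e-10)
        np.testing.assert_allclose(model.intercepts, vel.mean(axis=0),
                                   atol=1e-10)

    def test_duplicated_channel_warns_but_stays_finite(self, rng, caplog):
        e = rng.standard_normal((100, 2, 2))
        e = np.concatenate([e, e[:, :1, :]], axis=1)   # channel 0 duplicated
        ts = make_trialset([e], labels=["can"], rng=rng)
        with caplog.at_level("WARNING"):
            model = gd.fit_wiener(ts, outputs="joints")
        assert "rank-deficient" in caplog.text
        assert np.isfinite(model.coef).all()


class TestPredict:
    def test_zero_coefficients_predict_constant_intercept(self, rng):
        ts = make_trialset(rng=rng)
        model = gd.fit_wiener(ts, outputs="joints")
        model.coef[:] = 0.0
        preds = gd.predict(model, ts)
        for p in preds:
            np.testing.assert_allclose(
                p, np.tile(model.intercepts, (p.shape[0], 1)))

    def test_noiseless_prediction_correlates_perfectly(self, rng):
        eeg_tr = rng.standard_normal((300, 3, 2))
        eeg_te = rng.standard_normal((100, 3, 2))
        beta = rng.standard_normal((6, 15))
        ts_tr = make_trialset([eeg_tr], [eeg_tr.reshape(300, -1) @ beta],
                              ["can"], rng=rng)
        ts_te = make_trialset([eeg_te], [eeg_te.reshape(100, -1) @ beta],
                              ["cd"], rng=rng)
        model = gd.fit_wiener(ts_tr, outputs="joints")
        pred = gd.predict(model, ts_te)[0]
        obs = ts_te.stacked_velocities()
        for i in range(15):
            r = np.corrcoef(pred[:, i], obs[:, i])[0, 1]
            assert r > 1 - 1e-6

    def test_layout_mismatch_rejected(self, rng):
        ts = make_trialset(rng=rng)
        model = gd.fit_wiener(ts, outputs="joints")
        other = make_trialset(n_channels=4, rng=rng)
        with pytest.raises(ValueError):
            gd.predict(model, other)

    def test_training_fit_beats_heldout_on_average(self, rng):
        """Over 10 seeds, mean training r >= mean held-out r for noisy
        linear data (optimism of in-sample fit)."""
        tr_r, te_r = [], []
        for seed in range(10):
            g = np.random.default_rng(seed)
            beta = g.standard_normal((6, 1))
            e_tr = g.standard_normal((120, 3, 2))
            e_te = g.standard_normal((120, 3, 2))
            y_tr = e_tr.reshape(120, -1) @ beta + g.standard_normal((120, 1))
            y_te = e_te.reshape(120, -1) @ beta + g.standard_normal((120, 1))
            v_tr = np.tile(y_tr, (1, 15))
            v_te = np.tile(y_te, (1, 15))
            ts_tr = make_trialset([e_tr], [v_tr], ["can"], rng=g)
            ts_te = make_trialset([e_te], [v_te], ["cd"], rng=g)
            m = gd.fit_wiener(ts_tr, outputs="joints")
            p_tr = gd.predict(m, ts_tr)[0]
            p_te = gd.predict(m, ts_te)[0]
            tr_r.append(np.corrcoef(p_tr[:, 0], v_tr[:, 0])[0, 1])
            te_r.append(np.corrcoef(p_te[:, 0], v_te[:, 0])[0, 1])
        assert np.mean(tr_r) >= np.mean(te_r)


class TestCrossValidation:
    def test_fold_assignment_is_a_partition(self, tiny_processed):
        _, trials, _ = tiny_processed
        res = gd.cross_validate(trials, folds=8, seed=0)
        assert res.fold_assignment.min() >= 0
        assert res.fold_assignment.max() == 7
        assert len(res.fold_assignment) == trials.n_trials
        assert res.test_sample_counts.sum() == sum(e.shape[0]
                                                   for e in trials.eeg)

    def test_high_snr_synthetic_decodes_first_synergy(self, tiny_processed):
        _, trials, _ = tiny_processed
        res = gd.cross_validate(trials, folds=8, seed=0)
        assert res.median_r[0] >= 0.9
        assert np.all(np.abs(res.fold_r) <= 1.0)

    def test_pure_noise_eeg_decodes_at_chance(self, rng):
        ts = make_trialset(n_trials=16, t_len=150, n_channels=4, n_lags=3,
                           rng=rng)
        res = gd.cross_validate(ts, folds=4, seed=0, outputs="joints")
        assert np.median(np.abs(res.median_r)) <= 0.1

    def test_paper_faithful_mode_runs(self, tiny_processed):
        _, trials, _ = tiny_processed
        res = gd.cross_validate(trials, folds=8, seed=0, fold_safe=False)
        assert res.median_r[0] >= 0.9


class TestChannelRanking:
    def _model(self, coef, labels=None):
        c, l, o = coef.shape
        return gd.WienerModel(
            intercepts=np.zeros(o), coef=coef,
            channel_labels=labels or tuple(f"ch{i}" for i in range(c)),
            L=l - 1, output_names=tuple(f"PC{i+1}" for i in range(o)))

    def test_single_active_channel_ranked_first(self):
        coef = np.zeros((10, 4, 3))
        coef[7] = 1.0
        ranking = gd.rank_channels(self._model(coef))
        assert ranking.order[0] == 7
        assert ranking.r_n[7] > 0
        np.testing.assert_allclose(np.delete(ranking.r_n, 7), 0.0)

    def test_equal_coefficients_tie_broken_by_index(self):
        coef = np.full((5, 3, 3), 0.5)
        ranking = gd.rank_channels(self._model(coef))
        np.testing.assert_allclose(ranking.r_n, ranking.r_n[0])
        np.testing.assert_array_equal(ranking.order, np.arange(5))

    def test_matches_naive_double_loop(self, rng):
        coef = rng.standard_normal((6, 4, 3))
        ranking = gd.rank_channels(self._model(coef))
        for n in range(6):
            acc = 0.0
            for k in range(4):
                acc += np.sqrt(sum(coef[n, k, i] ** 2 for i in range(3)))
            np.testing.assert_allclose(ranking.r_n[n], acc / 4, rtol=1e-12)

    def test_requires_three_synergy_outputs(self, rng):
        coef = rng.standard_normal((3, 2, 2))
        with pytest.raises(ValueError):
            gd.rank_channels(self._model(coef))


class TestLagContributions:
    def _model(self, coef):
        c, l, o = coef.shape
        return gd.WienerModel(
            intercepts=np.zeros(o), coef=coef,
            channel_labels=tuple(f"ch{i}" for i in range(c)),
            L=l - 1, output_names=("PC1", "PC2", "PC3"))

    def test_single_lag_takes_all_contribution(self):
        coef = np.zeros((4, 11, 3))
        coef[:, 9, :] = 2.0
        out = gd.lag_contributions(self._model(coef))
        np.testing.assert_allclose(out.percent[9], 100.0)
        np.testing.assert_allclose(np.delete(out.percent, 9), 0.0)

    def test_uniform_coefficients_split_evenly(self):
        coef = np.full((4, 11, 3), 0.3)
        out = gd.lag_contributions(self._model(coef))
        np.testing.assert_allclose(out.percent, 100.0 / 11, rtol=1e-12)

    def test_percentages_sum_to_100_and_match_naive_loop(self, rng):
        coef = rng.standard_normal((5, 7, 3))
        out = gd.lag_contributions(self._model(coef))
        np.testing.assert_allclose(out.percent.sum(), 100.0, atol=1e-6)
        s = np.zeros((5, 7))
        for n in range(5):
            for k in range(7):
                s[n, k] = np.sqrt(sum(coef[n, k, i] ** 2 for i in range(3)))
        np.testing.assert_allclose(out.percent,
                                   100 * s.sum(axis=0) / s.sum(), rtol=1e-10)
        np.testing.assert_allclose(out.channel_lag_map, s, rtol=1e-10)

    def test_all_zero_coefficients_rejected(self):
        with pytest.raises(ValueError):
            gd.lag_contributions(self._model(np.zeros((3, 4, 3))))


class TestAccuracyCurve:
    def test_double_exponential_peak_recovered(self):
        """Curve sampled exactly from e^{-0.01 N} - e^{-0.3 N}: the integer
        argmax (dense-grid oracle) is N = 12."""
        n = np.arange(1, 59, dtype=float)
        y = _double_exp(n, 1.0, -0.01, -1.0, -0.3)
        dense = np.linspace(1, 58, 100001)
        oracle = int(round(dense[np.argmax(_double_exp(dense, 1.0, -0.01,
                                                       -1.0, -0.3))]))
        assert oracle == 12
        popt = _fit_double_exponential(n, y, seed=0)
        fitted = _double_exp(n, *popt)
        assert int(np.argmax(fitted)) + 1 == 12

    def test_monotone_curve_peaks_at_full_channel_count(self):
        n = np.arange(1, 30, dtype=float)
        y = 0.8 * (1 - np.exp(-0.1 * n))
        popt = _fit_double_exponential(n, y, seed=0)
        fitted = _double_exp(n, *popt)
        assert int(np.argmax(fitted)) + 1 == 29

    def test_informative_channels_dominate_curve(self, tiny_processed):
        """With 8 informative channels, accuracy with the top-8 ranked
        channels is near the curve's maximum and far above 1 channel."""
        _, trials, _ = tiny_processed
        model = gd.fit_full(trials)
        ranking = gd.rank_channels(model)
        informative = {"FC1", "C3", "CP5", "CP1", "CP2", "P3", "F3", "FC5"}
        assert set(ranking.top(4)) <= informative
        curve = gd.accuracy_vs_channels(trials, ranking, folds=4, seed=0)
        assert curve.curve.shape == (trials.n_channels, 3)
        assert 1 <= curve.peak_n[0] <= trials.n_channels
        pc1 = curve.curve[:, 0]
        assert pc1[7] > pc1[0]
        assert pc1[7] >= pc1.max() - 0.1


class TestSignificance:
    def _result(self, fold_r, n):
        folds, n_out = fold_r.shape
        return gd.DecodingResult(
            fold_r=fold_r, median_r=np.median(fold_r, axis=0),
            output_names=tuple(f"PC{i+1}" for i in range(n_out)),
            fold_assignment=np.zeros(1, dtype=int),
            test_sample_counts=np.full(folds, n),
            predictions=[], observed=[])

    def test_zero_correlation_gives_p_one(self):
        p = gd.assess_significance(self._result(np.zeros((3, 2)), 50), 10)
        np.testing.assert_allclose(p, 1.0)

    def test_strong_correlation_is_overwhelming(self):
        p = gd.assess_significance(self._result(np.full((1, 1), 0.99), 100), 1)
        assert p[0, 0] < 1e-10

    def test_bonferroni_scales_and_caps(self):
        res = self._result(np.full((1, 1), 0.4), 30)
        p1 = gd.assess_significance(res, 1)[0, 0]
        p7 = gd.assess_significance(res, 7)[0, 0]
        np.testing.assert_allclose(p7, min(1.0, 7 * p1), rtol=1e-12)
        assert gd.assess_significance(res, 10 ** 9)[0, 0] == 1.0

    def test_tiny_fold_rejected(self):
        with pytest.raises(ValueError):
            gd.assess_significance(self._result(np.zeros((1, 1)), 2), 1)


class TestFrontalOmissionControl:
    def test_dropping_frontal_channels_barely_changes_accuracy(
            self, small_processed):
        """Artifact-free synthetic data: removing Fp1/Fp2/AF7/AF8 shifts
        median r by < 0.05 for every synergy."""
        _, trials, _ = small_processed
        res_all = gd.cross_validate(trials, folds=8, seed=0)
        keep = [ch for ch in trials.channel_labels
                if ch not in gd.FRONTAL_CHANNELS]
        res_sub = gd.cross_validate(trials.select_channels(keep),
                                    folds=8, seed=0)
        assert np.abs(res_all.median_r - res_sub.median_r).max() < 0.05
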