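"""Parameter estimation: goodness of fit, initial guesses, round-trip
recovery in all three modes, noise robustness and determinism."""

from dataclasses import replace

import numpy as np
import pytest

from tensorcardiography import presets, synth
from tensorcardiography.fitting import (BeatFiducials, FitConfig,
                                        fit_extended, fit_rt_bulk,
                                        fit_rt_separate, goodness_of_fit,
                                        initial_guess)
from tensorcardiography.model import CDFComponent


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        y = np.array([0.0, 1.0, 0.5, -0.2])
        r2, sd = goodness_of_fit(y, y)
        assert r2 == 1.0
        assert sd == 0.0

    def test_mean_prediction_scores_zero(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        r2, _ = goodness_of_fit(y, np.full(4, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_hand_computed_sums_of_squares(self):
        # SS_res = 1, SS_tot = 5 -> r2 = 0.8; residuals (0,0,0,1) -> sd 0.5
        r2, sd = goodness_of_fit([0, 1, 2, 3], [0, 1, 2, 2])
        assert r2 == pytest.approx(0.8)
        assert sd == pytest.approx(0.5)

    def test_constant_signal_flagged(self):
        r2, sd = goodness_of_fit([1.0, 1.0, 1.0], [1.0, 0.9, 1.1])
        assert np.isnan(r2)
        assert sd >= 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            goodness_of_fit([1, 2], [1, 2, 3])


class TestInitialGuess:
    def test_close_to_truth_on_synthetic_beat(self, separate_mean_model,
                                              beat_factory):
        t, y, fid, truth = beat_factory(separate_mean_model)
        g = initial_guess(t, y, fid)
        assert abs(g.muRp - separate_mean_model.muRp) < 20.0
        assert abs(g.muTp - separate_mean_model.muTp) < 60.0

    def test_flat_signal_degenerates_gracefully(self):
        t = np.arange(0.0, 600.0)
        y = np.zeros_like(t)
        fid = BeatFiducials(80, 110, 140, 180, 370, 460)
        g = initial_guess(t, y, fid)
        assert g.kRp <= 1e-2
        r = fit_rt_separate(t, y, fid, FitConfig(restarts=1))
        assert r.model.kRp < 0.05 and r.model.kTn < 0.05

    def test_missing_landmark_named(self):
        fid = BeatFiducials(80, 110, 140, np.nan, 370, 460)
        with pytest.raises(ValueError, match="t_onset"):
            initial_guess(np.arange(600.0), np.zeros(600), fid)

    def test_out_of_order_fiducials_rejected(self):
        # T peak placed before the J point
        fid = BeatFiducials(80, 110, 140, 150, 130, 460)
        with pytest.raises(ValueError, match="order"):
            initial_guess(np.arange(600.0), np.zeros(600), fid)


class TestRoundTripRecovery:
    """Noiseless beats generated from published parameter sets must be
    recovered essentially exactly."""

    def test_separate_population_mean(self, separate_mean_model,
                                      beat_factory):
        t, y, fid, _ = beat_factory(separate_mean_model)
        r = fit_rt_separate(t, y, fid)
        truth = separate_mean_model
        assert r.converged
        assert r.r2_overall >= 0.9999
        assert r.metrics.muRTp == pytest.approx(truth.muTp - truth.muRp,
                                                rel=0.01)
        assert r.model.sigmaTn == pytest.approx(truth.sigmaTn, rel=0.01)
        assert r.model.kRp == pytest.approx(truth.kRp, rel=0.01)

    def test_bulk_population_mean_penalty(self, bulk_mean_model,
                                          beat_factory):
        t, y, fid, _ = beat_factory(bulk_mean_model)
        r = fit_rt_bulk(t, y, fid, FitConfig(mode="bulk", plateau="penalty"))
        truth = bulk_mean_model
        assert r.model.sigmaTp == pytest.approx(truth.sigmaTp, rel=0.01)
        assert r.metrics.muRTp == pytest.approx(truth.muTp - truth.muRp,
                                                rel=0.01)
        # the adaptive soft constraint must not equalise clearly unequal
        # plateau weights on a clean signal
        assert r.model.kTp == pytest.approx(truth.kTp, rel=0.01)

    def test_bulk_ers_case_block(self, ers_a1_model, beat_factory):
        t, y, fid, _ = beat_factory(ers_a1_model)
        r = fit_rt_bulk(t, y, fid, FitConfig(mode="bulk", plateau="penalty"))
        assert r.model.sigmaTn == pytest.approx(89.01, rel=0.01)
        assert r.metrics.muRTn == pytest.approx(266.65, rel=0.01)
        assert r.model.beta == pytest.approx(-0.08, abs=0.01)

    def test_hard_constraint_exact_equality(self, ers_a1_model,
                                            beat_factory):
        t, y, fid, _ = beat_factory(ers_a1_model)
        r = fit_rt_bulk(t, y, fid, FitConfig(mode="bulk", plateau="hard"))
        assert r.model.kTp == r.model.kRp
        assert r.model.kTn == r.model.kRn

    def test_cross_mode_consistency(self, beat_factory):
        # equal generating plateau weights: both modes can represent the
        # beat, so the recovered anodic duration must agree
        row = dict(presets.BULK_ALL_AVE)
        row["kTp"] = row["kRp"]
        row["kTn"] = row["kRn"]
        m = presets.beat_model_from_intervals(row, "bulk")
        t, y, fid, _ = beat_factory(m)
        rng = np.random.default_rng(11)
        yn = y + rng.normal(0, 0.02, y.shape)
        r_sep = fit_rt_separate(t, yn, fid)
        r_bulk = fit_rt_bulk(t, yn, fid, FitConfig(mode="bulk"))
        assert abs(r_bulk.metrics.muRTp - r_sep.metrics.muRTp) <= 5.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_randomised_models_recovered(self, seed):
        # draw a physiologic model inside the population spread and verify
        # interval metrics within 1%, spreads within 2%, weights within 1%
        rng = np.random.default_rng(seed)
        row = {k: presets.SEPARATE_ALL_AVE[k]
               + rng.uniform(-1, 1) * presets.SEPARATE_ALL_SD[k]
               for k in presets.SEPARATE_ALL_AVE}
        m = presets.beat_model_from_intervals(row, "separate")
        assert m.ordering_ok()
        y, truth = synth.synthesize_beat(m)
        t = np.arange(len(y)).astype(float)
        r = fit_rt_separate(t, y, BeatFiducials.from_truth(truth))
        assert r.metrics.muRTp == pytest.approx(m.muTp - m.muRp, rel=0.01)
        assert r.metrics.muRTn == pytest.approx(m.muTn - m.muRn, rel=0.01)
        for name in ("sigmaRp", "sigmaRn", "sigmaTp", "sigmaTn"):
            assert getattr(r.model, name) == pytest.approx(
                getattr(m, name), rel=0.02)
        for name in ("kRp", "kRn", "kTp", "kTn"):
            assert getattr(r.model, name) == pytest.approx(
                getattr(m, name), rel=0.01)


class TestNoiseAndDeterminism:
    def test_noisy_beats_fit_quality(self, separate_mean_model):
        # noise at 2% of the R amplitude; the decomposition acts as the
        # denoiser and keeps r2 high
        m = separate_mean_model
        r_amp = 1.835  # R-lobe amplitude of the population-mean beat
        rng = np.random.default_rng(100)
        r2s = []
        for _ in range(30):
            y, truth = synth.synthesize_beat(m, noise_sd=0.02 * r_amp,
                                             rng=rng)
            t = np.arange(len(y)).astype(float)
            r = fit_rt_separate(t, y, BeatFiducials.from_truth(truth),
                                FitConfig(restarts=2))
            r2s.append(r.r2_overall)
        assert np.median(r2s) >= 0.95

    def test_mu_interval_bias_small(self, separate_mean_model):
        m = separate_mean_model
        rng = np.random.default_rng(7)
        mus = []
        for _ in range(100):
            y, truth = synth.synthesize_beat(m, noise_sd=0.0367, rng=rng)
            t = np.arange(len(y)).astype(float)
            r = fit_rt_separate(t, y, BeatFiducials.from_truth(truth),
                                FitConfig(restarts=2))
            mus.append(r.metrics.muRTp)
        assert abs(np.mean(mus) - (m.muTp - m.muRp)) <= 2.0

    def test_bit_identical_given_seed(self, separate_mean_model,
                                      beat_factory):
        t, y, fid, _ = beat_factory(separate_mean_model, noise_sd=0.03,
                                    seed=5)
        cfg = FitConfig(seed=42)
        r1 = fit_rt_separate(t, y, fid, cfg)
        r2 = fit_rt_separate(t, y, fid, cfg)
        assert r1.model == r2.model
        assert r1.cost == r2.cost

    def test_window_too_short_rejected(self, separate_mean_model,
                                       beat_factory):
        t, y, fid, _ = beat_factory(separate_mean_model, fs=1000.0)
        cfg = FitConfig(min_window_samples=200)  # QRS window has ~60 samples
        with pytest.raises(ValueError, match="window"):
            fit_rt_separate(t, y, fid, cfg)


class TestExtendedMode:
    @staticmethod
    def _notched_beat(base):
        extra = (CDFComponent("anodic", "rising", 138.0, 3.0, 0.4),
                 CDFComponent("cathodic", "rising", 130.0, 3.0, 0.4))
        return replace(base, extras=(extra,))

    def test_notch_improves_fit(self, separate_mean_model, beat_factory):
        m = self._notched_beat(separate_mean_model)
        t, y, fid, _ = beat_factory(m)
        r4 = fit_rt_separate(t, y, fid)
        rx = fit_extended(t, y, fid,
                          FitConfig(mode="extended", n_extra_pairs=1))
        assert rx.r2_qrs > r4.r2_qrs
        assert rx.cost <= r4.cost + 1e-12  # nested-model monotonicity

    def test_parsimony_on_clean_beat(self, separate_mean_model,
                                     beat_factory):
        t, y, fid, _ = beat_factory(separate_mean_model)
        rx = fit_extended(t, y, fid,
                          FitConfig(mode="extended", n_extra_pairs=1))
        for pos, neg in rx.model.extras:
            assert pos.k <= 0.05 * rx.model.kRp
            assert pos.k >= 0.0 and neg.k >= 0.0

    def test_refuses_more_than_two_pairs(self, separate_mean_model,
                                         beat_factory):
        t, y, fid, _ = beat_factory(separate_mean_model)
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_extended(t, y, fid,
                         FitConfig(mode="extended", n_extra_pairs=3))
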