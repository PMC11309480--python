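"""Forward-model behaviour: component evaluation, waveforms, metrics,
repolarisation crossings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tensorcardiography import presets
from tensorcardiography.model import (BeatModel, CDFComponent,
                                      InvalidParameterError, derive_metrics,
                                      eval_component,
                                      find_repolarization_crossing,
                                      forward_bulk, forward_separate)
from tensorcardiography.synth import forward_full


def phi(z):
    """Independent Gaussian CDF oracle via the error function."""
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


class TestEvalComponent:
    def test_rising_at_mean_is_half_weight(self):
        c = CDFComponent("anodic", "rising", mu=10.0, sigma=5.0, k=2.0)
        assert eval_component(c, 10.0) == pytest.approx(1.0)

    def test_falling_tail_vanishes(self):
        c = CDFComponent("anodic", "falling", mu=10.0, sigma=5.0, k=2.0)
        assert eval_component(c, 1e6) == pytest.approx(0.0, abs=1e-12)
        assert eval_component(c, -1e6) == pytest.approx(2.0)

    def test_against_erf_oracle(self):
        # population-mean anodic R weight and spread, one sigma past the mean
        c = CDFComponent("anodic", "rising", mu=0.0, sigma=6.71, k=1.99)
        expected = 1.99 * phi(1.0)  # = 1.67428 to 5 decimals
        assert eval_component(c, 6.71) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.67428, abs=5e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(InvalidParameterError):
            CDFComponent("anodic", "rising", mu=0.0, sigma=0.0, k=1.0)
        with pytest.raises(InvalidParameterError):
            CDFComponent("anodic", "rising", mu=0.0, sigma=-3.0, k=1.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(InvalidParameterError):
            CDFComponent("anodic", "rising", mu=0.0, sigma=1.0, k=-0.1)

    @given(mu=st.floats(-100, 100), sigma=st.floats(0.5, 100),
           k=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_time(self, mu, sigma, k):
        t = np.linspace(mu - 5 * sigma, mu + 5 * sigma, 200)
        rising = eval_component(
            CDFComponent("anodic", "rising", mu, sigma, k), t)
        falling = eval_component(
            CDFComponent("anodic", "falling", mu, sigma, k), t)
        assert np.all(np.diff(rising) >= -1e-12)
        assert np.all(np.diff(falling) <= 1e-12)


class TestForwardSeparate:
    def test_identical_pair_cancels_to_level(self):
        m = BeatModel.from_params(
            "separate", muRp=100, muRn=100, muTp=300, muTn=300,
            sigmaRp=5, sigmaRn=5, sigmaTp=20, sigmaTn=20,
            kRp=1.5, kRn=1.5, kTp=0.8, kTn=0.8, beta_r=0.25, beta_t=-0.1)
        t = np.linspace(0, 500, 400)
        assert forward_separate(m, t, "R") == pytest.approx(
            np.full_like(t, 0.25))
        assert forward_separate(m, t, "T") == pytest.approx(
            np.full_like(t, -0.1))

    def test_left_tail_is_baseline(self, separate_mean_model):
        m = separate_mean_model
        y = forward_separate(m, [-1e5], "R")
        assert y[0] == pytest.approx(m.beta_r, abs=1e-12)

    def test_r_peak_sign_and_location(self, separate_mean_model):
        # dense-grid oracle: the R lobe peaks between the two depolarisation
        # means and is positive
        m = separate_mean_model
        t = np.arange(m.muRp - 30, m.muRn + 30, 0.1)
        y = forward_separate(m, t, "R")
        tp = t[np.argmax(y)]
        assert y.max() > 0
        assert m.muRp < tp < m.muRn

    def test_empty_grid_rejected(self, separate_mean_model):
        with pytest.raises(ValueError):
            forward_separate(separate_mean_model, [], "R")
        with pytest.raises(ValueError):
            forward_separate(separate_mean_model, np.arange(3), "X")


class TestForwardBulk:
    def test_closed_trapezoids_return_to_level(self):
        m = BeatModel.from_params(
            "bulk", muRp=100, muRn=120, muTn=350, muTp=400,
            sigmaRp=6, sigmaRn=5, sigmaTp=30, sigmaTn=45,
            kRp=1.9, kRn=1.8, kTp=1.9, kTn=1.8, beta=-0.05)
        assert forward_bulk(m, [5000.0])[0] == pytest.approx(-0.05, abs=1e-9)
        assert forward_bulk(m, [-5000.0])[0] == pytest.approx(-0.05, abs=1e-9)

    def test_plateau_is_model_st_level(self):
        # at a time where both R CDFs have saturated and both T CDFs have
        # not yet started, the waveform sits at kRp − kRn + β
        m = BeatModel.from_params(
            "bulk", muRp=100, muRn=120, muTn=400, muTp=440,
            sigmaRp=6, sigmaRn=5, sigmaTp=25, sigmaTn=40,
            kRp=2.0, kRn=1.9, kTp=2.0, kTn=1.9, beta=0.03)
        assert forward_bulk(m, [210.0])[0] == pytest.approx(
            2.0 - 1.9 + 0.03, abs=1e-3)

    def test_two_lobes_population_mean(self, bulk_mean_model):
        # sign-change scan above a 10%-of-peak threshold: exactly the R lobe
        # and the T lobe emerge (the ST plateau stays below threshold)
        t = np.arange(0, 600, 0.5)
        y = forward_bulk(bulk_mean_model, t)
        above = y > 0.1 * y.max()
        n_lobes = int(np.sum(np.diff(above.astype(int)) == 1) + above[0])
        assert n_lobes == 2

    def test_equivalence_with_separate_on_disjoint_windows(self):
        # with matching R/T weights the bulk waveform equals the sum of the
        # separate segment equations wherever the other segment's CDFs are
        # saturated/unstarted
        kw = dict(muRp=100, muRn=122, muTn=380, muTp=430,
                  sigmaRp=6.7, sigmaRn=5.8, sigmaTp=23, sigmaTn=35,
                  kRp=1.99, kRn=2.01, kTp=1.99, kTn=2.01)
        mb = BeatModel.from_params("bulk", beta=0.07, **kw)
        ms = BeatModel.from_params("separate", beta_r=0.2, beta_t=-0.3, **kw)
        tR = np.arange(70, 150, 0.5)   # R window: T CDFs ~0
        tT = np.arange(260, 520, 0.5)  # T window: R CDFs ~1
        for tw, seg in [(tR, "R"), (tT, "T")]:
            sep = forward_separate(ms, tw, seg)
            bulk = forward_bulk(mb, tw)
            beta_sep = ms.beta_r if seg == "R" else ms.beta_t
            np.testing.assert_allclose(bulk, sep - beta_sep + mb.beta,
                                       atol=1e-9)


class TestDeriveMetrics:
    def test_population_mean_row(self):
        m = BeatModel.from_params(
            "separate", muRp=0.0, muRn=22.18, muTn=253.88, muTp=307.36,
            sigmaRp=6.71, sigmaRn=5.83, sigmaTp=23.56, sigmaTn=54.29,
            kRp=1.99, kRn=2.01, kTp=0.8, kTn=0.8)
        met = derive_metrics(m)
        # printed interval metrics are internally consistent to 0.02 ms
        assert met.muRTp == pytest.approx(307.35, abs=0.02)
        assert met.muRTn == pytest.approx(231.70, abs=1e-9)
        assert met.muRpn == pytest.approx(22.18, abs=1e-9)
        assert met.muTpn == pytest.approx(53.48, abs=1e-9)

    def test_degenerate_all_equal(self):
        m = BeatModel.from_params(
            "separate", muRp=50, muRn=50, muTn=50, muTp=50,
            sigmaRp=1, sigmaRn=1, sigmaTp=1, sigmaTn=1,
            kRp=1, kRn=1, kTp=1, kTn=1)
        met = derive_metrics(m)
        assert (met.muRTp, met.muRTn, met.muRpn, met.muTpn) == (0, 0, 0, 0)

    @given(mus=st.lists(st.floats(-500, 500), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_interval_identity(self, mus):
        muRp, muRn, muTn, muTp = mus
        m = BeatModel.from_params(
            "separate", muRp=muRp, muRn=muRn, muTn=muTn, muTp=muTp,
            sigmaRp=5, sigmaRn=5, sigmaTp=20, sigmaTn=40,
            kRp=1, kRn=1, kTp=1, kTn=1)
        met = derive_metrics(m)
        assert met.muRpn + met.muRTn + met.muTpn == pytest.approx(
            met.muRTp, abs=1e-9)


def _crossing_oracle(m, step=0.1):
    """Independent dense-scan oracle using the erf-based CDF."""
    cTp, cTn = m.components["Tp"], m.components["Tn"]
    lo = cTn.mu - 3 * cTn.sigma
    hi = cTp.mu + 4 * cTp.sigma
    t = np.arange(lo, hi, step)
    fTp = np.array([cTp.k * (1 - phi((u - cTp.mu) / cTp.sigma)) for u in t])
    fTn = np.array([cTn.k * (1 - phi((u - cTn.mu) / cTn.sigma)) for u in t])
    d = fTp - fTn
    idx = np.nonzero((d[:-1] > 0) & (d[1:] < 0))[0]
    return None if idx.size == 0 else t[idx[-1]]


class TestRepolarizationCrossing:
    @staticmethod
    def _model(muTn, muTp, sTn, sTp, kTn=1.0, kTp=1.0):
        return BeatModel.from_params(
            "separate", muRp=0, muRn=20, muTn=muTn, muTp=muTp,
            sigmaRp=5, sigmaRn=5, sigmaTp=sTp, sigmaTn=sTn,
            kRp=1, kRn=1, kTp=kTp, kTn=kTn)

    def test_identical_curves_no_crossing(self):
        m = self._model(300, 300, 30, 30)
        assert not find_repolarization_crossing(m).crossed

    def test_shifted_equal_spread_no_crossing(self):
        # anodic curve strictly above cathodic everywhere when it lags with
        # the same spread and weight
        m = self._model(muTn=260, muTp=310, sTn=30, sTp=30)
        res = find_repolarization_crossing(m)
        assert not res.crossed
        assert _crossing_oracle(m) is None

    def test_wide_cathodic_tail_crosses(self, ers_a1_model):
        # ERS-case spreads: the cathodic tail outlasts the anodic descent
        res = find_repolarization_crossing(ers_a1_model)
        assert res.crossed
        oracle = _crossing_oracle(ers_a1_model)
        assert oracle is not None
        assert res.time == pytest.approx(oracle, abs=1.0)
        assert res.time > ers_a1_model.muTn  # late in the T window

    def test_crossing_condition_cathodic_above_after(self, ers_a1_model):
        res = find_repolarization_crossing(ers_a1_model)
        m = ers_a1_model
        t_after = res.time + 5.0
        fTp = m.kTp * (1 - phi((t_after - m.muTp) / m.sigmaTp))
        fTn = m.kTn * (1 - phi((t_after - m.muTn) / m.sigmaTn))
        assert fTn > fTp


class TestBeatModel:
    def test_ordering_check_flags_not_reorders(self):
        m = BeatModel.from_params(
            "separate", muRp=100, muRn=90, muTn=300, muTp=350,
            sigmaRp=5, sigmaRn=5, sigmaTp=20, sigmaTn=40,
            kRp=1, kRn=1, kTp=1, kTn=1)
        assert not m.ordering_ok()
        assert m.muRn == 90  # never silently reordered

    def test_shift_translates_means_only(self, separate_mean_model):
        m2 = separate_mean_model.shift(50.0)
        assert m2.muRp == separate_mean_model.muRp + 50.0
        assert m2.sigmaTn == separate_mean_model.sigmaTn
        t = np.arange(0, 600, 1.0)
        np.testing.assert_allclose(
            forward_full(separate_mean_model, t),
            forward_full(m2, t + 50.0), atol=1e-12)
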