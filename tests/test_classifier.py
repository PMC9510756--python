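"""Two-phase classifier: shape features, decision rules, template
extraction and correlation features against brute-force oracles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brainswitch import synth
from brainswitch.classifier import (ClassifierConfig, CorrelationFeatures,
                                    NoTrainingWindowsError, Template,
                                    WindowFeatures, calibrate_threshold,
                                    correlation_features, extract_training,
                                    phase1_decision, phase2_decision,
                                    window_features)
from brainswitch.signal_io import EpochSet


def _features_oracle(x, split, rate, split_s):
    """Exhaustive scan over all samples, no numpy reductions."""
    hind = list(x[split:])
    peak, k = min((v, i) for i, v in enumerate(hind))
    mean_fw = sum(x[:split]) / split
    mean_hw = sum(hind) / len(hind)
    t_ph = (split + k) / rate
    theta = math.atan((peak - mean_fw) / (t_ph - split_s))
    return peak, t_ph, mean_fw, mean_hw, mean_fw - mean_hw, theta


class TestWindowFeatures:
    def test_flat_window_all_zero(self, cfg):
        f = window_features(np.zeros(cfg.n_window), cfg)
        assert (f.peak_hw, f.d_mean, f.theta_erd) == (0.0, 0.0, 0.0)

    def test_single_dip_analytic_decline_angle(self):
        """A -1 % dip exactly 1 s after the split gives atan(-1)."""
        cfg = ClassifierConfig(split_s=1.5)
        x = np.zeros(cfg.n_window)
        x[160] = -1.0  # t = 2.5 s
        f = window_features(x, cfg)
        assert f.t_ph == pytest.approx(2.5)
        # mean_hw is slightly negative; theta uses mean_fw = 0
        assert f.theta_erd == pytest.approx(math.atan(-1.0), abs=1e-12)

    def test_matches_exhaustive_scan(self, cfg, rng):
        for _ in range(10):
            x = rng.standard_normal(cfg.n_window) * 40
            f = window_features(x, cfg)
            want = _features_oracle(list(x), cfg.n_split, cfg.rate,
                                    cfg.split_s)
            got = (f.peak_hw, f.t_ph, f.mean_fw, f.mean_hw, f.d_mean,
                   f.theta_erd)
            np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_earliest_sample_wins_ties(self, cfg):
        x = np.zeros(cfg.n_window)
        x[[150, 170]] = -5.0
        assert window_features(x, cfg).t_ph == pytest.approx(150 / 64)

    def test_wrong_length_rejected(self, cfg):
        with pytest.raises(ValueError):
            window_features(np.zeros(10), cfg)

    @given(peak=st.floats(-200, -1), mean_fw=st.floats(0, 50),
           t_ph=st.floats(2.02, 2.98))
    @settings(derandomize=True, max_examples=50)
    def test_decline_angle_formula(self, peak, mean_fw, t_ph):
        """theta is atan of (trough depth below the front mean) over the
        time since the front/hind split, for any feature combination."""
        cfg = ClassifierConfig()
        k = int(round((t_ph - 2.0) * cfg.rate))
        x = np.full(cfg.n_window, mean_fw)
        x[cfg.n_split + k] = peak
        f = window_features(x, cfg)
        want = math.atan((peak - mean_fw) / ((cfg.n_split + k) / cfg.rate - 2))
        assert f.theta_erd == pytest.approx(want, abs=1e-12)


def _wf(peak, mean_fw, mean_hw, t_ph=2.5, t_fw=2.0):
    theta = math.atan((peak - mean_fw) / (t_ph - t_fw))
    return WindowFeatures(peak, t_ph, mean_fw, mean_hw,
                          mean_fw - mean_hw, theta, t_fw)


class TestPhase1:
    def test_flat_roi_rejected(self, cfg):
        assert not phase1_decision(_wf(0.0, 0.0, 0.0), [], cfg)

    def test_deep_roi_beats_shallow_nonroi(self, cfg):
        roi = _wf(-40.0, -2.0, -30.0)
        others = [_wf(-10.0, -1.0, -8.0), _wf(-5.0, 0.5, -2.0)]
        assert phase1_decision(roi, others, cfg)

    def test_deeper_nonroi_is_pseudo_erd(self, cfg):
        """A stronger desynchronization off the ROI vetoes the window."""
        roi = _wf(-40.0, -2.0, -30.0)
        assert not phase1_decision(roi, [_wf(-60.0, -2.0, -45.0)], cfg)

    def test_empty_nonroi_degrades_to_roi_only(self, cfg):
        roi = _wf(-40.0, -2.0, -30.0)
        assert phase1_decision(roi, [], cfg)

    def test_positive_hind_mean_rejected_when_required(self):
        roi = _wf(-40.0, 30.0, 5.0)
        strict = ClassifierConfig(require_negative_mean_hw=True)
        lax = ClassifierConfig(require_negative_mean_hw=False)
        assert not phase1_decision(roi, [], strict)
        assert phase1_decision(roi, [], lax)


def _smooth(rng, n):
    x = np.cumsum(rng.standard_normal(n))
    return x - x.mean()


class TestCorrelationFeatures:
    def test_identity(self, cfg, rng):
        tpl = Template(_smooth(rng, cfg.n_window))
        c = correlation_features(tpl.values.copy(), tpl, cfg)
        assert c.cc_max == pytest.approx(1.0, abs=1e-12)
        assert c.cc_lat == 0.0
        assert c.r == pytest.approx(1.0, abs=1e-12)

    def test_known_delay_recovered(self, cfg, rng):
        """A window lagging the template by 5 samples puts the
        cross-correlation peak at +5/64 s."""
        base = _smooth(rng, cfg.n_window + 2 * cfg.n_lag)
        tpl = Template(base[cfg.n_lag + 5:cfg.n_lag + 5 + cfg.n_window])
        c = correlation_features(base, tpl, cfg)
        assert c.cc_lat == pytest.approx(5 / 64)
        assert c.cc_max == pytest.approx(1.0, abs=1e-12)

    def test_matches_bruteforce_lag_scan(self, cfg, rng):
        n, L = cfg.n_window, cfg.n_lag
        for _ in range(5):
            w = _smooth(rng, n)
            tpl = Template(_smooth(rng, n))
            c = correlation_features(w, tpl, cfg)
            best, best_lag = -np.inf, 0
            for lag in sorted(range(-L, L + 1), key=lambda l: (abs(l), l)):
                if lag >= 0:
                    cc = np.corrcoef(w[lag:], tpl.values[:n - lag])[0, 1]
                else:
                    cc = np.corrcoef(w[:n + lag], tpl.values[-lag:])[0, 1]
                if cc > best:
                    best, best_lag = cc, lag
            assert c.cc_max == pytest.approx(best, abs=1e-9)
            assert c.cc_lat == pytest.approx(best_lag / cfg.rate, abs=1e-12)
            want_r = np.corrcoef(w, tpl.values)[0, 1]
            assert c.r == pytest.approx(want_r, abs=1e-12)

    def test_pearson_matches_direct_formula(self, cfg, rng):
        w = rng.standard_normal(cfg.n_window)
        t = rng.standard_normal(cfg.n_window)
        c = correlation_features(w, Template(t), cfg)
        num = np.sum((w - w.mean()) * (t - t.mean()))
        den = np.sqrt(np.sum((w - w.mean()) ** 2) * np.sum((t - t.mean()) ** 2))
        assert c.r == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_flagged(self, cfg, rng):
        tpl = Template(_smooth(rng, cfg.n_window))
        c = correlation_features(np.full(cfg.n_window, 3.0), tpl, cfg)
        assert c.degenerate
        assert (c.cc_max, c.cc_lat, c.r) == (0.0, 0.0, 0.0)

    def test_amplitude_scale_invariance(self, cfg, rng):
        """Correlation features ignore signal magnitude entirely."""
        w = _smooth(rng, cfg.n_window)
        tpl = Template(_smooth(rng, cfg.n_window))
        ref = correlation_features(w, tpl, cfg)
        for c_scale in (1e-3, 0.5, 250.0):
            got = correlation_features(c_scale * w, tpl, cfg)
            assert got.cc_max == pytest.approx(ref.cc_max, abs=1e-10)
            assert got.cc_lat == ref.cc_lat
            assert got.r == pytest.approx(ref.r, abs=1e-10)

    def test_zero_lag_in_search_implies_ccmax_ge_r(self, cfg, rng):
        for _ in range(10):
            w = _smooth(rng, cfg.n_window)
            tpl = Template(_smooth(rng, cfg.n_window))
            c = correlation_features(w, tpl, cfg)
            assert c.cc_max >= c.r - 1e-12


class TestPhase2:
    def _roi(self, r=0.9, cc_max=0.95, cc_lat=0.0):
        return CorrelationFeatures(cc_max, cc_lat, r)

    def test_template_match_with_noise_nonroi(self, cfg):
        noise = [CorrelationFeatures(0.4, 0.1, 0.2)]
        assert phase2_decision(self._roi(), noise, cfg)

    def test_threshold_boundary(self, cfg):
        eps = 1e-9
        assert not phase2_decision(self._roi(r=cfg.r_threshold - eps), [], cfg)
        assert phase2_decision(self._roi(r=cfg.r_threshold), [], cfg)

    def test_excessive_lag_rejected(self, cfg):
        assert not phase2_decision(self._roi(cc_lat=0.3), [], cfg)

    def test_nonroi_more_template_like_rejected(self, cfg):
        """A contamination channel matching the template better vetoes."""
        stronger = [CorrelationFeatures(0.99, 0.0, 0.97)]
        assert not phase2_decision(self._roi(), stronger, cfg)


def _erd_epochs(cfg, trough_at=1.0, n_trials=3, depth=0.5, noise=0.05,
                seed=7):
    """Band-filtered-style epochs: 11 Hz tone whose envelope drops so the
    band-power trough lands at ``trough_at`` seconds post-cue."""
    rng = np.random.default_rng(seed)
    rate, n = cfg.rate, 512
    t = np.arange(n) / rate - 4.0
    out = np.empty((n_trials, 1, n))
    for tr in range(n_trials):
        env = synth._envelope(n, rate, [trough_at - 1.0 + 4.0], 0.5, 1.0,
                              depth)
        osc = 10.0 * np.sin(2 * np.pi * 11 * (t + 4.0) + rng.uniform(0, 7))
        out[tr, 0] = env * osc + noise * rng.standard_normal(n)
    return EpochSet(out, rate, ["C3"], (-4.0, 4.0))


class TestExtractTraining:
    def test_template_trough_in_hind_area(self, cfg):
        eps = _erd_epochs(cfg, trough_at=1.0)
        tpl = extract_training(eps, "C3", [], cfg)
        assert tpl.n_windows >= 1
        assert np.argmin(tpl.values) >= cfg.n_split
        assert tpl.values.min() < -30

    def test_late_trough_excluded(self, cfg):
        eps = _erd_epochs(cfg, trough_at=3.2)
        with pytest.raises(NoTrainingWindowsError):
            extract_training(eps, "C3", [], cfg)

    def test_single_epoch_template_is_that_window(self, cfg):
        eps = _erd_epochs(cfg, trough_at=1.0, n_trials=1)
        tpl = extract_training(eps, "C3", [], cfg)
        assert tpl.n_windows == 1

    def test_rate_mismatch_rejected(self, cfg):
        eps = _erd_epochs(cfg)
        eps.rate = 128.0
        with pytest.raises(ValueError):
            extract_training(eps, "C3", [], cfg)


class TestCalibrateThreshold:
    def test_all_noise_keeps_prior_threshold(self, calibration, cfg, montage):
        plan, tpl = calibration["plan"], calibration["template"]
        sched = synth.make_schedule("calibration", "MI", 8)
        rec = synth.generate_background(montage, sched.session_dur, 128.0,
                                        seed=99)
        with pytest.warns(RuntimeWarning):
            thr = calibrate_threshold(rec, sched, plan, tpl, cfg,
                                      sensitivity_floor=80.0)
        assert thr == cfg.r_threshold

    def test_returns_grid_value_meeting_floor(self, calibration, cfg):
        from brainswitch import metrics
        from brainswitch.engine import run_session

        plan, tpl = calibration["plan"], calibration["template"]
        rec, sched = calibration["recordings"]["MI"]
        thr = calibrate_threshold(rec, sched, plan, tpl, cfg,
                                  sensitivity_floor=20.0)
        assert 0.30 <= thr <= 0.95
        res = run_session(rec, sched, plan, tpl,
                          ClassifierConfig(r_threshold=thr))
        assert metrics.sensitivity(res.tp, res.n_trials) >= 20.0
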