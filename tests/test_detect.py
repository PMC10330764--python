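"""Confidence value, variance, state machine and bin selection."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fmcw_vitals as fv
from fmcw_vitals import preprocess
from fmcw_vitals.detect import (
    ConfidenceConfig,
    StateBuffer,
    StateConfig,
    StateTracker,
    accumulate_confidence,
    calibrate_presence_threshold,
    confidence_value,
    range_bin_variance,
    select_target_bin,
    update_state,
)
from fmcw_vitals.sim import STATE_MOTION, STATE_STABLE, STATE_UNMANNED


def cfg(**kw) -> ConfidenceConfig:
    base = dict(guard=1, train=2, scan_start=0, threshold=1.0)
    base.update(kw)
    return ConfidenceConfig(**base)


class TestConfidenceValue:
    def test_hand_oracle_peak_profile(self):
        # energies: peak 8^2=64; per-side training averages 1 each -> PT=2
        V, D = confidence_value(np.array([1, 1, 1, 1, 8, 1, 1, 1, 1.0]), cfg())
        assert D == 4
        assert V == pytest.approx(32.0, abs=1e-6)

    def test_flat_profile_gives_half(self):
        V, _ = confidence_value(np.full(16, 3.0), cfg(guard=2, train=4))
        assert V == pytest.approx(0.5, abs=1e-6)

    def test_all_zero_profile(self):
        V, D = confidence_value(np.zeros(16), cfg(scan_start=2))
        assert V == 0.0
        assert D == 2  # argmax tie -> lowest scanned bin

    def test_circular_wrap_at_edges(self):
        # peak at bin 0: training cells wrap to the far end of the profile
        profile = np.array([8.0, 1, 1, 2, 2, 2, 2, 1, 1])
        V, D = confidence_value(profile, cfg())
        assert D == 0
        # left cells are bins -2 % 9 = 7 and -3 % 9 = 6 (energy 1, 4)
        left = (profile[7] ** 2 + profile[6] ** 2) / 2
        right = (profile[2] ** 2 + profile[3] ** 2) / 2
        assert V == pytest.approx(64 / (left + right), rel=1e-9)

    def test_profile_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            confidence_value(np.ones(5), cfg(guard=2, train=4))

    def test_scan_range_respected(self):
        profile = np.array([9.0, 1, 1, 1, 5, 1, 1, 1, 1])
        _, D = confidence_value(profile, cfg(scan_start=2))
        assert D == 4  # bin 0 excluded from the scan

    @given(st.floats(min_value=0.01, max_value=1e4))
    @settings(deadline=None)
    def test_scale_invariance(self, scale):
        profile = np.array([1, 2, 1, 1, 8, 1, 3, 1, 1.0])
        V1, D1 = confidence_value(profile, cfg())
        V2, D2 = confidence_value(scale * profile, cfg())
        assert D1 == D2
        assert V2 == pytest.approx(V1, rel=1e-6)

    @given(st.floats(min_value=8.0, max_value=100.0))
    @settings(deadline=None)
    def test_monotone_in_peak_energy(self, peak):
        base = np.array([1, 2, 1, 1, 8, 1, 3, 1, 1.0])
        V0, _ = confidence_value(base, cfg())
        boosted = base.copy()
        boosted[4] = peak
        V1, _ = confidence_value(boosted, cfg())
        assert V1 >= V0 - 1e-12


class TestAccumulation:
    def test_trailing_sum(self):
        assert accumulate_confidence(np.array([2.0, 3, 5]), 3) == 10.0

    def test_window_of_one_is_latest(self):
        assert accumulate_confidence(np.array([2.0, 3, 5]), 1) == 5.0

    def test_short_history_uses_available(self):
        assert accumulate_confidence(np.array([4.0]), 8) == 4.0

    def test_all_zero(self):
        assert accumulate_confidence(np.zeros(5), 3) == 0.0

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            accumulate_confidence(np.array([1.0]), 0)


class TestThresholdCalibration:
    def test_zero_variance_background(self):
        assert calibrate_presence_threshold(np.full(12, 5.0), k=3) == 5.0

    def test_two_sample_hand_value(self):
        thr = calibrate_presence_threshold(np.array([4.0, 6.0]), k=3)
        assert thr == pytest.approx(5 + 3 * np.sqrt(2), rel=1e-12)

    def test_k_zero_gives_mean(self):
        assert calibrate_presence_threshold(np.array([1.0, 2, 3]), k=0) == 2.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            calibrate_presence_threshold(np.array([5.0]))


class TestRangeBinVariance:
    def test_constant_bins(self):
        assert range_bin_variance(np.array([7, 7, 7, 7])) == 0.0

    def test_hand_values(self):
        assert range_bin_variance(np.array([25, 25, 26, 26])) == pytest.approx(1 / 3)
        assert range_bin_variance(np.array([20, 30])) == pytest.approx(50.0)

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            range_bin_variance(np.array([25]))


class TestStateMachine:
    scfg = StateConfig()
    ccfg = ConfidenceConfig(threshold=10.0)

    def run(self, raws, buffer=None):
        buffer = buffer or StateBuffer(maxlen=self.scfg.buffer_len)
        out = []
        for raw in raws:
            vsum = 100.0 if raw != STATE_UNMANNED else 0.0
            s2 = 0.0 if raw == STATE_STABLE else 10.0
            state, buffer = update_state(vsum, s2, self.ccfg, self.scfg, buffer)
            out.append(state)
        return out, buffer

    def test_uniform_buffer_emits_that_state(self):
        out, _ = self.run([STATE_STABLE] * 40)
        assert out[-1] == STATE_STABLE
        out, _ = self.run([STATE_UNMANNED] * 40)
        assert out[-1] == STATE_UNMANNED

    def test_split_buffer_retains_previous_state(self):
        buffer = StateBuffer(maxlen=40,
                             raw=[STATE_STABLE] * 20 + [STATE_MOTION] * 19,
                             emitted=STATE_MOTION)
        state, _ = update_state(100.0, 10.0, self.ccfg, self.scfg, buffer)
        # buffer now 20/20: no state exceeds 80%, so motion is retained
        assert state == STATE_MOTION

    def test_switch_needs_supermajority(self):
        out, buffer = self.run([STATE_STABLE] * 40)
        # 32 of 40 motion frames is exactly 80%: not "exceeds", no switch
        out, buffer = self.run([STATE_MOTION] * 32, buffer)
        assert out[-1] == STATE_STABLE
        out, _ = self.run([STATE_MOTION], buffer)
        assert out[-1] == STATE_MOTION


class TestSelectTargetBin:
    def test_constant_run(self):
        scfg = StateConfig()
        out = select_target_bin(np.full(10, 25), [STATE_STABLE] * 10, scfg)
        assert np.all(out == 25.0)

    def test_outlier_suppressed_by_median(self):
        scfg = StateConfig()
        D = np.array([25] * 39 + [60])
        out = select_target_bin(D, [STATE_STABLE] * 40, scfg)
        assert out[-1] == 25.0

    def test_non_stable_frames_emit_nothing(self):
        scfg = StateConfig()
        states = [STATE_STABLE] * 5 + [STATE_MOTION] * 5
        out = select_target_bin(np.full(10, 25), states, scfg)
        assert np.all(np.isfinite(out[:5]))
        assert np.all(np.isnan(out[5:]))


class TestTrackerOnScenario:
    def test_streaming_equals_batch_and_split(self, confidence_cfg,
                                              three_state_cube):
        scfg = StateConfig()
        profiles = preprocess.preprocess_cube(three_state_cube)
        batch = StateTracker(confidence_cfg, scfg).track(profiles)

        stream = StateTracker(confidence_cfg, scfg)
        rec = [stream.step(m) for m in profiles.magnitude]
        assert [r["state"] for r in rec] == batch.state
        assert np.array_equal([r["Vsum"] for r in rec], batch.Vsum)

        # split the cube in half, carrying the clutter-filter state across
        half = three_state_cube.n_frames // 2
        c1 = fv.IFFrameCube(three_state_cube.data[:half], three_state_cube.config)
        c2 = fv.IFFrameCube(three_state_cube.data[half:], three_state_cube.config)
        p1 = preprocess.preprocess_cube(c1)
        p2 = preprocess.preprocess_cube(c2, init_state=p1.filter_state)
        split_tracker = StateTracker(confidence_cfg, scfg)
        t1 = split_tracker.track(p1)
        t2 = split_tracker.track(p2)
        assert t1.state + t2.state == batch.state
        assert np.array_equal(np.concatenate([t1.s2, t2.s2]), batch.s2)
        sel = np.concatenate([t1.selected_bin, t2.selected_bin])
        assert np.array_equal(np.isnan(sel), np.isnan(batch.selected_bin))
        assert np.array_equal(sel[~np.isnan(sel)],
                              batch.selected_bin[~np.isnan(batch.selected_bin)])

    def test_emitted_states_match_truth(self, radar, confidence_cfg,
                                        three_state_cube):
        profiles = preprocess.preprocess_cube(three_state_cube)
        track = fv.track_states(profiles, confidence_cfg, StateConfig())
        truth = np.asarray(three_state_cube.truth_state)
        pred = track.state_codes
        fs = radar.frame_rate
        excl = np.zeros(len(truth), bool)
        for t_s in (20.0, 80.0):
            i = int(t_s * fs)
            excl[max(0, i - int(2.5 * fs)): i + int(2.5 * fs)] = True
        assert np.mean(pred[~excl] == truth[~excl]) >= 0.90
        for t_s, code in ((20.0, 2), (80.0, 1)):
            i = int(t_s * fs)
            latency = np.argmax(pred[i:] == code) / fs
            assert (pred[i:] == code).any() and latency <= 2.5

    def test_selected_bin_present_iff_stable(self, confidence_cfg,
                                             three_state_cube):
        profiles = preprocess.preprocess_cube(three_state_cube)
        track = fv.track_states(profiles, confidence_cfg, StateConfig())
        stable = np.array([s == STATE_STABLE for s in track.state])
        assert np.all(np.isfinite(track.selected_bin[stable]))
        assert np.all(np.isnan(track.selected_bin[~stable]))


class TestAccumulationReducesFalseAlarms:
    def test_false_detection_rate_drops_after_accumulation(
            self, background_profiles):
        # per-frame thresholding vs v-frame accumulation at matched mean level
        ccfg = ConfidenceConfig()
        V = np.array([confidence_value(m, ccfg)[0]
                      for m in background_profiles.magnitude])
        v = ccfg.accum
        Vsum = np.convolve(V, np.ones(v), mode="valid")
        thr_frame = np.quantile(V, 0.9)
        rate_frame = np.mean(V > thr_frame)
        rate_accum = np.mean(Vsum > v * thr_frame)
        assert rate_accum < rate_frame
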