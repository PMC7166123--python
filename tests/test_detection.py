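"""Velocity estimation, thresholding and the event-detection cascade."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mainseq.detection import (
    DetectionParams,
    GazeRecording,
    VelocityTrace,
    compute_velocity,
    cyclopean_merge,
    detect_events,
    detect_fixations,
    detect_microsaccades,
    detect_saccades,
    endpoint_displacement,
    estimate_thresholds,
    event_kinematics,
)
from mainseq.errors import DegenerateThresholdError, ValidationError
from mainseq.synth import ScheduledEvent, StreamSpec, gen_stream

RATE = 500.0
DT = 1.0 / RATE


def _mono(t, x, y, rate=RATE, trial="trial"):
    return GazeRecording(t=t, x=x, y=y, nominal_rate=rate, trial_id=trial)


class TestCyclopeanMerge:
    def test_identical_eyes_pass_through(self):
        t = np.arange(3) * DT
        rec = GazeRecording(t=t, xl=np.ones(3), yl=np.zeros(3), xr=np.ones(3), yr=np.zeros(3))
        out = cyclopean_merge(rec)
        np.testing.assert_array_equal(out.x, 1.0)

    def test_arithmetic_mean_of_eyes(self):
        t = np.arange(3) * DT
        rec = GazeRecording(t=t, xl=np.zeros(3), yl=np.zeros(3), xr=np.full(3, 2.0), yr=np.full(3, 4.0))
        out = cyclopean_merge(rec)
        np.testing.assert_array_equal(out.x, 1.0)
        np.testing.assert_array_equal(out.y, 2.0)

    def test_monocular_passes_through_unchanged(self):
        rec = _mono(np.arange(3) * DT, np.arange(3.0), np.zeros(3))
        assert cyclopean_merge(rec) is rec

    def test_single_eye_samples_pass_through_and_empty_flagged_missing(self):
        t = np.arange(3) * DT
        xl = np.array([1.0, np.nan, np.nan])
        rec = GazeRecording(t=t, xl=xl, yl=xl, xr=np.array([3.0, 5.0, np.nan]), yr=np.array([3.0, 5.0, np.nan]))
        out = cyclopean_merge(rec)
        np.testing.assert_array_equal(out.x[:2], [2.0, 5.0])
        assert np.isnan(out.x[2])


class TestComputeVelocity:
    def test_constant_position_zero_velocity(self):
        t = np.arange(10) * DT
        v = compute_velocity(t, np.full(10, 3.3), np.full(10, -1.1))
        assert np.all(v.vx[2:-2] == 0) and np.all(v.vy[2:-2] == 0)
        assert np.all(np.isnan(v.vx[:2])) and np.all(np.isnan(v.vx[-2:]))

    @pytest.mark.parametrize("speed", [5.0, 40.0])
    def test_linear_ramp_six_dt_recovers_exact_slope(self, speed):
        t = np.arange(20) * DT
        v = compute_velocity(t, speed * t, np.zeros(20), mode="six_dt", nominal_rate=RATE)
        np.testing.assert_allclose(v.vx[2:-2], speed, rtol=1e-12)

    @pytest.mark.parametrize("speed", [5.0, 40.0])
    def test_linear_ramp_timestamp_mode_scales_by_1_5(self, speed):
        """The timestamp denominator spans 4 sampling periods while the
        stencil numerator sums to 6 periods worth of displacement."""
        t = np.arange(20) * DT
        v = compute_velocity(t, speed * t, np.zeros(20), mode="timestamps")
        np.testing.assert_allclose(v.vx[2:-2], 1.5 * speed, rtol=1e-12)

    def test_short_segment_rejected(self):
        t = np.arange(4) * DT
        with pytest.raises(ValidationError):
            compute_velocity(t, t, t)


class TestThresholds:
    def test_hand_computed_medians(self):
        v = VelocityTrace(vx=np.array([-1.0, 0.0, 1.0]), vy=np.array([1.0, 0.0, -1.0]))
        thr = estimate_thresholds(v, lam=2.5)
        assert thr.sigma_x == pytest.approx(1.0) and thr.sigma_y == pytest.approx(1.0)
        assert thr.eta_x == pytest.approx(2.5)

    def test_lambda_six_gives_six_sigma(self):
        rng = np.random.default_rng(0)
        v = VelocityTrace(vx=rng.normal(size=500), vy=rng.normal(size=500))
        thr = estimate_thresholds(v, lam=6.0)
        assert thr.eta_x == pytest.approx(6.0 * thr.sigma_x)
        assert thr.eta_y == pytest.approx(6.0 * thr.sigma_y)

    @given(scale=st.floats(0.1, 100.0))
    def test_homogeneous_in_velocity_scale(self, scale):
        rng = np.random.default_rng(7)
        vx, vy = rng.normal(size=200), rng.normal(size=200)
        base = estimate_thresholds(VelocityTrace(vx=vx, vy=vy), 6.0)
        scaled = estimate_thresholds(VelocityTrace(vx=scale * vx, vy=scale * vy), 6.0)
        assert scaled.sigma_x == pytest.approx(scale * base.sigma_x, rel=1e-9)
        assert scaled.eta_y == pytest.approx(scale * base.eta_y, rel=1e-9)

    def test_degenerate_dispersion_raises(self):
        v = VelocityTrace(vx=np.ones(10), vy=np.ones(10))
        with pytest.raises(DegenerateThresholdError):
            estimate_thresholds(v, 6.0)


class TestFixations:
    def test_jittered_stationary_recording_is_one_fixation(self):
        rng = np.random.default_rng(3)
        n = 1000
        t = np.arange(n) * DT
        rec = _mono(t, rng.normal(0, 0.01, n), rng.normal(0, 0.01, n))
        fix = detect_fixations(rec, DetectionParams())
        assert len(fix) == 1
        assert fix[0].duration > 0.98 * t[-1]

    def test_two_epochs_split_by_fast_transition(self):
        rng = np.random.default_rng(4)
        n = 500
        t = np.arange(2 * n + 10) * DT
        x = np.concatenate([
            rng.normal(0, 0.01, n),
            np.linspace(0, 10, 10),  # ~500 deg/s ramp
            10 + rng.normal(0, 0.01, n),
        ])
        rec = _mono(t, x, np.zeros_like(x))
        fix = detect_fixations(rec, DetectionParams())
        assert len(fix) == 2

    def test_empty_recording(self):
        rec = GazeRecording(t=np.array([]), x=np.array([]), y=np.array([]))
        assert detect_fixations(rec, DetectionParams()) == []

    def test_binocular_input_rejected(self):
        t = np.arange(8) * DT
        rec = GazeRecording(t=t, xl=np.zeros(8), yl=np.zeros(8), xr=np.zeros(8), yr=np.zeros(8))
        with pytest.raises(ValidationError):
            detect_fixations(rec, DetectionParams())


def _drift_stream(seed, duration=2.0, drift_sd=9.0, events=()):
    spec = StreamSpec(duration=duration, rate=RATE, drift_sd=drift_sd,
                      event_schedule=events, seed=seed)
    return gen_stream(spec)


class TestMicrosaccades:
    def test_false_positive_rate_on_pure_drift(self):
        """Drift alone should essentially never cross a 6-sigma threshold."""
        total_events, total_time = 0, 0.0
        for seed in range(100):
            rec, _ = _drift_stream(seed)
            ev = detect_microsaccades(rec.t, rec.x, rec.y, DetectionParams())
            total_events += len(ev)
            total_time += rec.t[-1]
        assert total_events / total_time < 0.05

    def test_single_injected_event_detected_with_amplitude(self):
        ev = ScheduledEvent.create(1.0, 0.5, 0.0, peak_velocity=90.0, gamma=30)
        rec, truth = _drift_stream(11, events=(ev,))
        out = detect_microsaccades(rec.t, rec.x, rec.y, DetectionParams())
        assert len(out) == 1
        assert out[0].amplitude == pytest.approx(0.5, rel=0.20)
        assert abs(out[0].onset - truth[0].onset) < 0.01

    def test_lockout_merges_overshoot_pairs(self):
        """A second burst 10 ms after the first falls inside the 20 ms
        lockout and must not be reported separately."""
        e1 = ScheduledEvent.create(1.0, 0.5, 0.0, peak_velocity=90.0, gamma=30)
        t_gap = e1.window()[1] + 0.010
        e2 = ScheduledEvent(onset=t_gap - e1.profile.support()[0], amplitude=0.3,
                            direction_deg=180.0, profile=e1.profile)
        rec, _ = _drift_stream(12, events=(e1, e2))
        out = detect_microsaccades(rec.t, rec.x, rec.y, DetectionParams(lockout=0.020))
        assert len(out) == 1
        out2 = detect_microsaccades(rec.t, rec.x, rec.y, DetectionParams(lockout=0.0))
        assert len(out2) == 2


class TestSaccades:
    def test_isolated_over_threshold_samples_are_not_saccades(self):
        """The edge rule: detected events are exactly the over-threshold runs
        of length >= 2, so naturally occurring single-sample crossings are
        dropped."""
        from mainseq.detection import _elliptic_over, _runs

        found_singleton = False
        p = DetectionParams(lambda_saccade=2.2)  # sensitive enough for crossings
        for seed in range(10):
            rng = np.random.default_rng(600 + seed)
            n = 2000
            t = np.arange(n) * DT
            rec = _mono(t, np.cumsum(rng.normal(0, 9.0, n)) * DT,
                        np.cumsum(rng.normal(0, 9.0, n)) * DT)
            vel = compute_velocity(rec.t, rec.x, rec.y)
            thr = estimate_thresholds(vel, p.lambda_saccade)
            runs = _runs(_elliptic_over(vel, thr))
            singles = [r for r in runs if r.size == 1]
            edges = [r for r in runs if r.size >= 2]
            found_singleton = found_singleton or bool(singles)
            out = detect_saccades(rec, p)
            assert len(out) == len(edges)
            for e, r in zip(out, edges):
                assert e.onset == pytest.approx(rec.t[r[0]])
        assert found_singleton  # the rule was actually exercised

    def test_five_injected_saccades_recovered_with_onset_accuracy(self):
        amps = [2.0, 3.0, 4.0, 5.0, 6.0]
        events = tuple(
            ScheduledEvent.create(0.5 + i * 0.8, a, 72.0 * i, peak_velocity=150 * a, gamma=30)
            for i, a in enumerate(amps)
        )
        rec, truth = _drift_stream(31, duration=5.0, events=events)
        out = detect_saccades(rec, DetectionParams())
        assert len(out) == 5
        for det, tr in zip(sorted(out, key=lambda e: e.onset), truth):
            assert abs(det.onset - tr.onset) <= 2 * DT

    def test_empty_and_flat_recordings_give_no_events(self):
        empty = GazeRecording(t=np.array([]), x=np.array([]), y=np.array([]))
        assert detect_saccades(empty, DetectionParams()) == []
        t = np.arange(100) * DT
        flat = _mono(t, np.zeros(100), np.zeros(100))
        assert detect_saccades(flat, DetectionParams()) == []


class TestEventKinematics:
    def test_straight_horizontal_event(self):
        t = np.arange(10) * DT
        x = np.linspace(0, 1, 10)
        y = np.zeros(10)
        vel = compute_velocity(t, x, y, mode="six_dt", nominal_rate=RATE)
        amp, peak, dur = event_kinematics(t, x, y, vel, np.arange(10))
        assert amp == pytest.approx(1.0)
        assert dur == pytest.approx(9 * DT)
        assert endpoint_displacement(x, y, np.arange(10)) == pytest.approx(1.0)

    def test_translation_invariance(self):
        t = np.arange(10) * DT
        x = np.linspace(0, 1, 10)
        y = 0.2 * x
        vel = compute_velocity(t, x, y, mode="six_dt", nominal_rate=RATE)
        idx = np.arange(10)
        a1 = event_kinematics(t, x, y, vel, idx)
        a2 = event_kinematics(t, x + 10, y - 5, compute_velocity(t, x + 10, y - 5, "six_dt", RATE), idx)
        assert a1 == pytest.approx(a2)

    def test_gamma_profile_event_kinematics_recovered(self):
        """A noiseless 3 deg event with 300 deg/s peak yields those values
        back through the six_dt velocity convention."""
        ev = ScheduledEvent.create(0.2, 3.0, 0.0, peak_velocity=300.0, gamma=30)
        # 2 kHz keeps the 5-sample stencil window short relative to the
        # event, so the moving average barely attenuates the peak
        rate = 2000.0
        spec = StreamSpec(duration=0.6, rate=rate, drift_sd=0.0, event_schedule=(ev,), seed=0)
        rec, _ = gen_stream(spec)
        vel = compute_velocity(rec.t, rec.x, rec.y, mode="six_dt", nominal_rate=rate)
        idx = np.arange(len(rec))
        amp, peak, _ = event_kinematics(rec.t, rec.x, rec.y, vel, idx)
        assert amp == pytest.approx(3.0, rel=0.02)
        assert peak == pytest.approx(300.0, rel=0.05)


class TestCascadeInvariants:
    @pytest.fixture
    def busy_recording(self):
        micro = tuple(
            ScheduledEvent.create(0.4 + 0.5 * i, 0.4 + 0.03 * i, 45.0 * i, peak_velocity=85.0, gamma=30)
            for i in range(6)
        )
        rec, truth = _drift_stream(41, duration=4.0, events=micro)
        return rec, truth

    def test_offset_and_trial_relabel_invariance(self, busy_recording):
        rec, _ = busy_recording
        p = DetectionParams()
        base = detect_events(rec, p)
        shifted = GazeRecording(t=rec.t, x=rec.x + 7.5, y=rec.y - 3.0,
                                nominal_rate=rec.nominal_rate, trial_id="other")
        moved = detect_events(shifted, p)
        assert len(base) == len(moved)
        for a, b in zip(base, moved):
            assert a.kind == b.kind
            assert a.onset == pytest.approx(b.onset)
            assert a.amplitude == pytest.approx(b.amplitude, rel=1e-9)

    def test_spatial_scaling_scales_kinematics_linearly(self, busy_recording):
        rec, _ = busy_recording
        p = DetectionParams()
        base = {round(e.onset, 4): e for e in detect_events(rec, p) if e.kind == "microsaccade"}
        scaled_rec = GazeRecording(t=rec.t, x=2.0 * rec.x, y=2.0 * rec.y,
                                   nominal_rate=rec.nominal_rate, trial_id=rec.trial_id)
        scaled = {round(e.onset, 4): e for e in detect_events(scaled_rec, p) if e.kind == "microsaccade"}
        assert base.keys() == scaled.keys() and base
        for k in base:
            assert scaled[k].amplitude == pytest.approx(2.0 * base[k].amplitude, rel=1e-9)
            assert scaled[k].peak_velocity == pytest.approx(2.0 * base[k].peak_velocity, rel=1e-9)

    def test_structure_microsaccades_inside_fixations_no_overlap(self, busy_recording):
        rec, _ = busy_recording
        p = DetectionParams()
        events = detect_events(rec, p)
        fix = [e for e in events if e.kind == "fixation"]
        micro = sorted((e for e in events if e.kind == "microsaccade"), key=lambda e: e.onset)
        assert micro
        for m in micro:
            assert any(f.onset <= m.onset and m.offset <= f.offset for f in fix)
        for kind in ("fixation", "microsaccade", "saccade"):
            same = sorted((e for e in events if e.kind == kind), key=lambda e: e.onset)
            for a, b in zip(same, same[1:]):
                assert b.onset > a.offset
        for a, b in zip(micro, micro[1:]):
            assert b.onset - a.offset >= p.lockout - 1e-12

    def test_recall_and_amplitude_correlation_on_injected_events(self):
        """Events well above threshold are nearly always recovered and their
        measured amplitudes track the injected ones."""
        rng = np.random.default_rng(99)
        detected_amp, injected_amp = [], []
        hits = total = 0
        for seed in range(12):
            amps = rng.uniform(0.3, 1.2, size=5)
            events = tuple(
                ScheduledEvent.create(0.4 + 0.6 * i, float(a), float(rng.uniform(0, 360)),
                                      peak_velocity=float(60 + 60 * a), gamma=30)
                for i, a in enumerate(amps)
            )
            rec, truth = _drift_stream(1000 + seed, duration=3.6, events=events)
            out = detect_microsaccades(rec.t, rec.x, rec.y, DetectionParams())
            total += len(truth)
            for tr in truth:
                match = [d for d in out if d.onset <= tr.offset and d.offset >= tr.onset]
                if match:
                    hits += 1
                    detected_amp.append(match[0].amplitude)
                    injected_amp.append(tr.amplitude)
        assert hits / total >= 0.95
        r = np.corrcoef(injected_amp, detected_amp)[0, 1]
        assert r >= 0.95
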