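"""State segmentation and event detection, with a brute-force onset oracle."""

import numpy as np
import pytest

from tvrpipe.config import IMAGING_RATE_HZ, PipelineConfig
from tvrpipe.segmentation import (
    EventSet,
    assign_states,
    detect_onsets,
    detect_running,
    detect_whisking,
    segment_session,
    select_perturbations,
    split_touch_events,
    touch_onsets,
)


def brute_force_onsets(b, n_off=4, n_on=4):
    """Exhaustive scan: onset at i iff b[i-n_off:i] all 0 and b[i:i+n_on] all 1."""
    b = np.asarray(b, dtype=int)
    out = []
    for i in range(n_off, len(b) - n_on + 1):
        if b[i] == 1 and not b[i - n_off:i].any() and b[i:i + n_on].all():
            out.append(i)
    return out


class TestDetectWhisking:
    def test_constant_angle_never_whisks(self):
        w, _ = detect_whisking(np.full(4000, 42.0))
        assert not w.any()

    def test_large_sinusoid_whisks(self):
        """10-deg 10-Hz oscillation has windowed std ~ 7.1 deg > 2.5."""
        t = np.arange(4000) / 200.0
        w, env = detect_whisking(10.0 * np.sin(2 * np.pi * 10.0 * t))
        interior = slice(5, -5)
        assert w[interior].all()
        assert np.median(env[interior]) == pytest.approx(10.0 / np.sqrt(2), rel=0.05)

    def test_small_sinusoid_does_not_whisk(self):
        """3-deg amplitude: std ~ 2.1 deg stays below the 2.5-deg threshold."""
        t = np.arange(4000) / 200.0
        w, _ = detect_whisking(3.0 * np.sin(2 * np.pi * 10.0 * t))
        assert not w.any()


class TestDetectRunning:
    def test_zero_speed(self):
        r, _ = detect_running(np.zeros(4000))
        assert not r.any()

    def test_constant_speed(self):
        r, s = detect_running(np.full(4000, 5.0))
        assert r.all()
        assert np.allclose(s, 5.0, atol=0.01)

    def test_step_transition_within_smoothing_shift(self):
        """A 0->5 cm/s step is detected within 0.8 s of the true step."""
        speed = np.zeros(4800)
        speed[2400:] = 5.0
        r, _ = detect_running(speed)
        onset_frames = np.nonzero(r)[0]
        assert len(onset_frames)
        t_detected = onset_frames[0] / IMAGING_RATE_HZ
        assert abs(t_detected - 60.0) <= 0.8


class TestAssignStates:
    def test_labels(self):
        tl = assign_states(np.array([1, 0, 1, 0]), np.array([1, 1, 0, 0]))
        assert list(tl.state) == ["run_whisk", "run_nowhisk", "rest_whisk", "rest_nowhisk"]

    def test_occupancy_partitions(self):
        rng = np.random.default_rng(0)
        tl = assign_states(rng.integers(0, 2, 500), rng.integers(0, 2, 500))
        assert sum(tl.occupancy().values()) == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            assign_states(np.zeros(5), np.zeros(6))


class TestDetectOnsets:
    def test_single_onset(self):
        b = np.r_[np.zeros(10), np.ones(10)]
        ev = detect_onsets(b)
        assert list(ev.times) == [1.0]
        assert list(ev.ends) == [2.0]

    def test_short_off_gap_rejected(self):
        b = np.r_[np.ones(10), np.zeros(3), np.ones(10)]
        ev = detect_onsets(b)
        assert len(ev) == 0

    def test_matches_brute_force_on_random_sequences(self):
        """1,000 random binary sequences: detector equals exhaustive scan."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            b = (rng.uniform(size=60) < rng.uniform(0.2, 0.8)).astype(int)
            ev = detect_onsets(b)
            expected = brute_force_onsets(b)
            assert [int(round(t * 10)) for t in ev.times] == expected

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        b = (rng.uniform(size=100) < 0.5).astype(int)
        ev = detect_onsets(np.r_[np.zeros(13), b])
        base = detect_onsets(np.r_[np.zeros(5), b])
        shifted = [t + 0.8 for t in base.times]
        assert np.allclose(ev.times, shifted)

    def test_whisk_truncated_by_running(self):
        whisk = np.r_[np.zeros(10), np.ones(30)]
        run = np.r_[np.zeros(25), np.ones(15)]
        ev = detect_onsets(whisk, truncate_at=run)
        assert list(ev.times) == [1.0]
        assert list(ev.ends) == [2.5]  # running starts before whisking stops


class TestTouchOnsets:
    def test_single_stage_move_with_contact(self):
        stage = np.zeros(100)
        stage[30:33] = 1
        contact = np.zeros(100)
        contact[32:80] = 1
        touch, control = touch_onsets(stage, contact)
        assert list(touch.times) == [3.0]
        assert list(touch.ends) == [8.0]
        assert len(control) == 0

    def test_no_stage_movement(self):
        touch, control = touch_onsets(np.zeros(50), np.zeros(50))
        assert len(touch) == 0 and len(control) == 0

    def test_contactless_motion_is_sound_control(self):
        stage = np.zeros(100)
        stage[30:33] = 1
        touch, control = touch_onsets(stage, np.zeros(100))
        assert len(touch) == 0
        assert list(control.times) == [3.0]

    def test_matches_generator_ground_truth(self, closed_loop_session):
        touch, _ = touch_onsets(
            closed_loop_session.stage_moving_flag, closed_loop_session.contact_flag
        )
        assert np.allclose(
            touch.times, closed_loop_session.ground_truth["touch_onset_times"]
        )


class TestSplitTouchEvents:
    def _events(self, times):
        return EventSet("touch_onset", np.array(times), np.array(times) + 5.0)

    @pytest.mark.parametrize(
        "speed,expect_running,expect_resting",
        [(5.0, 1, 0), (0.0, 0, 1), (1.5, 0, 0)],
    )
    def test_speed_bands(self, speed, expect_running, expect_resting):
        ev = self._events([10.0])
        run, rest = split_touch_events(ev, np.full(300, speed))
        assert (len(run), len(rest)) == (expect_running, expect_resting)

    def test_groups_disjoint_and_exclusion_band(self):
        rng = np.random.default_rng(2)
        times = np.arange(10.0, 200.0, 12.0)
        speed = rng.uniform(0, 4, 2500)
        ev = self._events(times)
        run, rest = split_touch_events(ev, speed)
        assert set(run.times).isdisjoint(rest.times)
        kept = set(run.times) | set(rest.times)
        dropped = set(times) - kept
        ctx = {t: c for t, c in zip(*_context(ev, speed))}
        for t in dropped:
            assert 1.0 <= ctx[t] <= 2.0

    def test_out_of_range_window_dropped(self):
        ev = self._events([0.5])  # pre-window would start before the recording
        run, rest = split_touch_events(ev, np.full(300, 5.0))
        assert len(run) == 0 and len(rest) == 0


def _context(ev, speed):
    from tvrpipe.segmentation import _event_context_speed

    out, ctx = _event_context_speed(ev, speed, (-1.0, 4.0), IMAGING_RATE_HZ)
    return out.times, ctx


class TestSelectPerturbations:
    def test_halt_during_running_retained(self):
        flag = np.zeros(300)
        flag[100:120] = 1
        run, rest = select_perturbations(flag, np.full(300, 10.0))
        assert list(run.times) == [10.0] and len(rest) == 0

    def test_halt_while_stationary_goes_to_resting_set(self):
        flag = np.zeros(300)
        flag[100:120] = 1
        run, rest = select_perturbations(flag, np.zeros(300))
        assert len(run) == 0 and list(rest.times) == [10.0]

    def test_matches_generator_halts(self, perturbed_session):
        b = perturbed_session
        _, speed = detect_running(b.run_speed)
        run, rest = select_perturbations(b.perturbation_flag, speed[: b.n_frames])
        all_detected = sorted(list(run.times) + list(rest.times))
        truth = sorted(b.ground_truth["perturbation_times"])
        # every retained event is a true halt
        assert set(all_detected) <= set(np.round(truth, 6))


class TestPipelineOccupancy:
    def test_state_occupancy_matches_ground_truth(self, closed_loop_session):
        """Pipeline-estimated occupancy vs generative bouts, within the
        smoothing-induced boundary error (<= 1.5 s per bout edge)."""
        b = closed_loop_session
        tl = segment_session(b)
        run_est = np.mean(tl.running)
        run_true = np.mean(b.ground_truth["running_10hz"])
        n_edges = 2 * len(b.ground_truth["run_bouts"])
        bound = 1.5 * n_edges / b.duration_s
        assert abs(run_est - run_true) <= bound

    def test_running_without_whisking_is_rare(self, closed_loop_session):
        tl = segment_session(closed_loop_session)
        assert tl.occupancy()["run_nowhisk"] < 0.01
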