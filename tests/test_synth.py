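"""Generator properties: bout occupancy, touch logic, calcium forward model."""

import numpy as np
import pytest

import tvrpipe.synth as synth
from tvrpipe.synth import BehaviorConfig, NeuronSpec, generate_behavior, generate_fluorescence


class TestBehaviorConfig:
    def test_rejects_nonpositive_trial_duration(self):
        with pytest.raises(ValueError):
            BehaviorConfig(trial_duration=0)

    def test_rejects_inverted_iti_range(self):
        with pytest.raises(ValueError):
            BehaviorConfig(iti_range=(5.0, 3.0))

    def test_rejects_touch_distance_out_of_range(self):
        with pytest.raises(ValueError):
            BehaviorConfig(condition="closed_loop", touch_distance=60.0)

    def test_rejects_perturbations_without_touch(self):
        with pytest.raises(ValueError):
            generate_behavior(BehaviorConfig(condition="no_touch", include_perturbations=True))


class TestGenerateBehavior:
    def test_no_bouts_means_no_running(self):
        b = generate_behavior(BehaviorConfig(n_trials=4, run_bout_rate=0.0, rng_seed=0,
                                             condition="no_touch"))
        assert np.all(np.abs(b.run_speed) < 0.5)
        assert not np.any(b.ground_truth["running_10hz"])

    def test_closed_loop_contact_at_distance_over_speed(self, monkeypatch):
        """Constant 5 cm/s and a 10-cm touch distance put the stage-in 2 s
        after trial start."""
        monkeypatch.setattr(
            synth, "_speed_trace", lambda rng, bouts, n40, prof: np.full(n40, 5.0)
        )
        cfg = BehaviorConfig(n_trials=3, touch_distance=10.0, rng_seed=1)
        b = generate_behavior(cfg)
        for (ts, _), t_stage in zip(b.trial_intervals, b.ground_truth["touch_onset_times"]):
            assert t_stage - ts == pytest.approx(2.0, abs=0.1)

    def test_contact_follows_cumulative_distance(self, closed_loop_session):
        """In every closed-loop trial, contact begins only once the
        within-trial run distance reaches the configured touch distance."""
        b = closed_loop_session
        dist_target = b.ground_truth["config"]["touch_distance"]
        contact = np.asarray(b.contact_flag, dtype=bool)
        for ts, te in b.trial_intervals:
            j0, j1 = int(ts * 10), int(te * 10)
            trial_contact = np.nonzero(contact[j0:j1])[0]
            if len(trial_contact) == 0:
                continue
            t_contact = (j0 + trial_contact[0]) / 10.0
            i0 = int(ts * 40)
            dist = np.cumsum(b.run_speed[i0: int(t_contact * 40)]) / 40.0
            assert dist[-1] >= dist_target * 0.95

    def test_texture_speed_tracks_run_speed_in_contact(self, closed_loop_session):
        b = closed_loop_session
        in_contact = np.asarray(b.contact_flag, dtype=bool) & ~np.asarray(
            b.perturbation_flag, dtype=bool
        )
        speed10 = b.run_speed.reshape(-1, 4).mean(axis=1)
        assert np.allclose(b.texture_speed[in_contact], speed10[in_contact])

    def test_open_loop_texture_decoupled(self, open_loop_session):
        b = open_loop_session
        in_contact = np.asarray(b.contact_flag, dtype=bool)
        speed10 = b.run_speed.reshape(-1, 4).mean(axis=1)
        r = np.corrcoef(b.texture_speed[in_contact], speed10[in_contact])[0, 1]
        assert abs(r) < 0.5

    def test_perturbation_is_two_seconds_inside_contact(self, perturbed_session):
        b = perturbed_session
        flag = np.asarray(b.perturbation_flag, dtype=int)
        onsets = np.nonzero(np.diff(np.concatenate([[0], flag])) == 1)[0]
        offsets = np.nonzero(np.diff(np.concatenate([flag, [0]])) == -1)[0]
        assert len(onsets) >= 3
        for i, j in zip(onsets, offsets):
            assert (j + 1 - i) == pytest.approx(20, abs=1)   # 2 s at 10 Hz
            assert b.contact_flag[i - 1] == 1                # halt lies within contact
            assert np.all(b.texture_speed[i: j + 1] == 0.0)

    def test_running_implies_whisking(self, closed_loop_session):
        gt = closed_loop_session.ground_truth
        run = np.asarray(gt["running_10hz"], dtype=bool)
        whisk = np.asarray(gt["whisking_10hz"], dtype=bool)
        assert np.mean(run & ~whisk) < 0.01

    def test_same_seed_is_bit_identical(self):
        cfg = BehaviorConfig(n_trials=4, rng_seed=5)
        a, b = generate_behavior(cfg), generate_behavior(cfg)
        assert np.array_equal(a.run_speed, b.run_speed)
        assert np.array_equal(a.whisker_angle, b.whisker_angle)
        assert np.array_equal(a.contact_flag, b.contact_flag)
        assert a.trial_intervals == b.trial_intervals

    def test_run_occupancy_matches_analytic_rate(self):
        """Monte-Carlo occupancy of the semi-Markov bout process vs the
        closed form b*d/60, within 10 points absolute over 20 seeds."""
        cfg0 = BehaviorConfig()
        target = cfg0.run_occupancy
        occ = []
        for seed in range(20):
            b = generate_behavior(
                BehaviorConfig(n_trials=25, condition="no_touch", rng_seed=100 + seed)
            )
            occ.append(np.mean(b.ground_truth["running_10hz"]))
        assert abs(np.mean(occ) - target) < 0.10


class TestGenerateFluorescence:
    def test_silent_neuron_is_flat(self):
        b = generate_behavior(BehaviorConfig(n_trials=3, rng_seed=2))
        spec = NeuronSpec(baseline_rate=0.0, noise_sd=0.0, f0=100.0, background=10.0)
        s = generate_fluorescence(b, [spec], 0)
        assert np.allclose(s.fluo[0], 110.0)

    def test_steady_state_dff_equals_rate_A_tau(self):
        """Constant 10 Hz with A=0.10, tau=0.35 settles at dF/F = r*A*tau."""
        b = generate_behavior(BehaviorConfig(n_trials=20, condition="no_touch",
                                             run_bout_rate=0.0, rng_seed=3))
        specs = [
            NeuronSpec(baseline_rate=10.0, kernel_amplitude=0.10, kernel_tau=0.35,
                       noise_sd=0.0)
            for _ in range(10)
        ]
        s = generate_fluorescence(b, specs, 4)
        dff = (s.fluo - 10.0) / 100.0 - 1.0
        mean_ss = dff[:, 50:].mean()
        assert mean_ss == pytest.approx(10.0 * 0.10 * 0.35, rel=0.05)

    def test_default_kernel_parameters_in_published_ranges(self):
        rng = np.random.default_rng(0)
        specs = [NeuronSpec.make("run", rng) for _ in range(50)]
        amps = np.array([s.kernel_amplitude for s in specs])
        taus = np.array([s.kernel_tau for s in specs])
        assert np.all((amps >= 0.08) & (amps <= 0.11))
        assert np.all((taus >= 0.3) & (taus <= 0.4))

    def test_negative_rate_clipped_with_warning(self):
        b = generate_behavior(BehaviorConfig(n_trials=3, rng_seed=4))
        spec = NeuronSpec(baseline_rate=1.0, run_gain=-5.0, noise_sd=0.0)
        with pytest.warns(UserWarning, match="clipped"):
            s = generate_fluorescence(b, [spec], 5)
        assert np.all(s.fluo[0] >= spec.background)

    def test_rejects_empty_specs(self, closed_loop_session):
        with pytest.raises(ValueError):
            generate_fluorescence(closed_loop_session, [], 0)

    def test_kernel_sum_is_amplitude_times_tau_over_dt(self):
        k = synth.calcium_kernel(0.1, 0.35, dt=0.1)
        assert k.sum() == pytest.approx(0.1 * 0.35 / 0.1, rel=1e-3)
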