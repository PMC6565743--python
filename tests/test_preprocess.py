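"""dF/F baseline, noise sigma, SNR, slice-trace fits, rate conversion."""

import numpy as np
import pytest

from tvrpipe.preprocess import (
    bleach_correct,
    compute_baseline_noise,
    compute_dff,
    compute_snr,
    fit_decay_tau,
    rate_from_steady_state,
    trace_stats,
)
from tvrpipe.synth import BehaviorConfig, NeuronSpec, generate_behavior, generate_fluorescence


class TestComputeDff:
    def test_constant_trace(self):
        dff, f0 = compute_dff(np.full(200, 100.0), background=10.0)
        assert f0 == pytest.approx(90.0)
        assert np.allclose(dff, 0.0, atol=1e-12)

    def test_two_level_trace_plateau(self):
        """10% of frames quiet at 100, the rest at 200: baseline locks onto
        the quiet floor and the plateau sits at dF/F = 1."""
        trace = np.full(2000, 200.0)
        trace[:200] = 100.0
        dff, f0 = compute_dff(trace, background=0.0)
        plateau = np.median(dff[300:])
        assert plateau == pytest.approx(1.0, abs=0.02)

    def test_recovers_generator_f0(self):
        b = generate_behavior(BehaviorConfig(n_trials=8, rng_seed=7))
        spec = NeuronSpec(baseline_rate=0.5, f0=120.0, background=15.0)
        s = generate_fluorescence(b, [spec], 8)
        _, f0 = compute_dff(s.fluo[0], background=15.0)
        assert f0 == pytest.approx(120.0, rel=0.02)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(np.ones(20), 0.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            compute_dff(np.full(100, 50.0), background=60.0)

    def test_background_invariance(self):
        rng = np.random.default_rng(1)
        trace = 100.0 + rng.normal(0, 2.0, 500)
        dff_a, _ = compute_dff(trace, background=0.0)
        dff_b, _ = compute_dff(trace + 25.0, background=25.0)
        assert np.allclose(dff_a, dff_b)


class TestBaselineNoise:
    def test_zero_trace(self):
        assert compute_baseline_noise(np.zeros(200)) == 0.0

    def test_iid_gaussian_order_statistic(self):
        """For unit white noise over 30 min, the 1st percentile of the
        5-s-window SDs lands in [0.72, 0.80] (range frozen from an
        independent rolling-SD simulation over 20 seeds)."""
        rng = np.random.default_rng(2)
        sigma = compute_baseline_noise(rng.standard_normal(18000))
        assert 0.72 <= sigma <= 0.80

    def test_finds_quiet_block(self):
        """A 15-s block of sd-0.5 noise amid sd-2 noise pins sigma near 0.5
        (enough windows fit fully inside the quiet stretch)."""
        rng = np.random.default_rng(3)
        trace = rng.normal(0, 2.0, 3000)
        trace[1000:1150] = rng.normal(0, 0.5, 150)
        assert compute_baseline_noise(trace) == pytest.approx(0.5, rel=0.25)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compute_baseline_noise(np.zeros(30))

    def test_monotone_in_noise_amplitude(self):
        rng = np.random.default_rng(4)
        base = rng.standard_normal(4000)
        sigmas = [compute_baseline_noise(amp * base) for amp in (0.5, 1.0, 2.0, 4.0)]
        assert np.all(np.diff(sigmas) > 0)


class TestSnr:
    def test_constant_dff(self):
        assert compute_snr(np.full(100, 3.0), 1.0) == pytest.approx(3.0)

    def test_standard_normal_gives_95th_quantile(self):
        rng = np.random.default_rng(5)
        snr = compute_snr(rng.standard_normal(100000), 1.0)
        assert snr == pytest.approx(1.645, abs=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        d = rng.standard_normal(1000)
        assert compute_snr(d, 0.7) == pytest.approx(compute_snr(2 * d, 1.4))

    def test_zero_sigma_rejected(self):
        with pytest.raises(ValueError):
            compute_snr(np.ones(10), 0.0)


class TestSliceTraces:
    rate = 16.67  # slice imaging frame rate

    def _transient(self, n, peak_idx, amp, tau):
        t = np.arange(n) / self.rate
        y = np.zeros(n)
        post = t >= t[peak_idx]
        y[post] = amp * np.exp(-(t[post] - t[peak_idx]) / tau)
        return y

    def test_no_bleach_leaves_trace_untouched(self):
        y = 0.05 + self._transient(300, 100, 0.5, 0.35)
        corrected, _ = bleach_correct(y, 100 / self.rate, self.rate)
        assert np.max(np.abs(corrected - y)) < 1e-6

    def test_pure_bleach_flattens_to_zero(self):
        t = np.arange(300) / self.rate
        y = 0.3 * np.exp(-0.05 * t)
        corrected, (scale, rate) = bleach_correct(y, 8.0, self.rate)
        assert np.max(np.abs(corrected)) < 1e-6
        assert rate == pytest.approx(0.05, rel=1e-3)

    def test_transient_amplitude_preserved_under_bleach(self):
        """0.01/s bleach needs tens of seconds to be identifiable; on a 48-s
        trace the transient amplitude comes back within 3%."""
        t = np.arange(800) / self.rate
        transient = self._transient(800, 150, 0.5, 0.35)
        y = transient + 0.2 * np.exp(-0.01 * t)
        corrected, _ = bleach_correct(y, 150 / self.rate, self.rate)
        assert np.max(corrected) == pytest.approx(0.5, rel=0.03)

    def test_exclusion_window_too_wide_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct(np.ones(20), 0.5, self.rate)

    def test_decay_tau_noiseless(self):
        y = 0.4 * np.exp(-np.arange(100) / self.rate / 0.35)
        fit = fit_decay_tau(y, self.rate)
        assert fit.converged and fit.tau == pytest.approx(0.35, abs=1e-4)

    def test_decay_tau_at_slice_rate(self):
        y = 0.3 * np.exp(-np.arange(50) / self.rate / 0.30)
        assert fit_decay_tau(y, self.rate).tau == pytest.approx(0.30, abs=0.01)

    def test_decay_tau_noise_monte_carlo(self):
        rng = np.random.default_rng(7)
        taus = []
        for _ in range(100):
            y = 0.4 * np.exp(-np.arange(100) / self.rate / 0.35)
            taus.append(fit_decay_tau(y + rng.normal(0, 0.04, 100), self.rate).tau)
        assert np.median(np.abs(np.array(taus) / 0.35 - 1)) < 0.10


class TestRateConversion:
    def test_zero(self):
        assert rate_from_steady_state(0.0, 0.1, 0.35) == 0.0

    @pytest.mark.parametrize(
        "amp,tau,expected_rounded",
        [(0.08, 0.3, 21), (0.11, 0.4, 11)],
    )
    def test_published_50pct_bounds(self, amp, tau, expected_rounded):
        """A 50% steady-state dF/F maps to 11-21 Hz over the kernel ranges."""
        assert round(rate_from_steady_state(0.5, amp, tau)) == expected_rounded

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            rate_from_steady_state(0.5, 0.0, 0.35)

    def test_inverts_generator_steady_state(self):
        """Forward model at constant rate then rate_from_steady_state on the
        measured dF/F recovers the rate within 10%."""
        b = generate_behavior(BehaviorConfig(n_trials=12, condition="no_touch",
                                             run_bout_rate=0.0, rng_seed=9))
        r, amp, tau = 8.0, 0.09, 0.33
        spec = NeuronSpec(baseline_rate=r, kernel_amplitude=amp, kernel_tau=tau)
        s = generate_fluorescence(b, [spec], 10)
        dff, stats = trace_stats(s.fluo[0], spec.background)
        # F0 sits at the quiet floor, so steady state is the overall mean
        # dF/F relative to the true baseline
        dff_true = (s.fluo[0] - spec.background) / spec.f0 - 1.0
        est = rate_from_steady_state(float(dff_true[50:].mean()), amp, tau)
        assert est == pytest.approx(r, rel=0.10)
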