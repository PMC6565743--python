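"""Synthetic tactile virtual-reality sessions with known ground truth.

The generator emulates head-fixed mice on a treadmill whose whiskers touch a
rotating textured wall: 20-s trials separated by 3-5 s inter-trial intervals;
alternating rest/run bouts in which running is always accompanied by
whisking; a texture that moves into whisker reach once the animal has run a
set distance (5-50 cm) and then rotates at the run speed (closed loop), at an
independent speed (open loop), or stays out of reach (no-touch sound
control); and 2-s texture-halt perturbations at a random time within contact.

Calcium fluorescence is generated forward from per-neuron firing rates:
Poisson spikes at 10 Hz frames convolved with a single-action-potential
kernel of fractional amplitude ``A`` (default range 8-11%) and exponential
decay ``tau`` (0.3-0.4 s), assuming linear summation, plus Gaussian noise.
The kernel is integrated over each frame bin so that a constant rate ``r``
yields a steady-state dF/F of exactly ``r * A * tau``.

Behavioral bouts follow a semi-Markov alternation with exponential
durations, so state occupancy has a closed form: with ``run_bout_rate`` b
bouts/min of mean duration d seconds, running occupies ``b * d / 60`` of the
session.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .bundle import SessionBundle
from .config import IMAGING_RATE_HZ, SPEED_RATE_HZ, WHISKER_RATE_HZ

CONDITIONS = ("no_touch", "closed_loop", "open_loop", "perturbed_closed_loop")
TOUCH_CONDITIONS = ("closed_loop", "open_loop", "perturbed_closed_loop")

_GRID = 0.1  # all interval times are snapped to the 10-Hz frame grid


@dataclass
class BehaviorConfig:
    """Parameters of the behavioral/stimulus forward model."""

    trial_duration: float = 20.0          # s
    iti_range: tuple[float, float] = (3.0, 5.0)
    condition: str = "closed_loop"
    n_trials: int = 40
    run_bout_rate: float = 3.0            # bouts/min
    run_bout_duration: float = 10.0       # s, mean of exponential
    rest_whisk_prob: float = 0.5          # chance a rest gap contains a whisk bout
    speed_profile: tuple[float, float] = (10.0, 3.0)  # cm/s (mean, sd) per bout
    touch_distance: float = 20.0          # cm run before the texture moves in
    perturbation_duration: float = 2.0    # s texture halt
    include_perturbations: bool | None = None  # None -> derived from condition
    layer: str = "L2/3"
    rng_seed: int = 0

    def __post_init__(self):
        if self.trial_duration <= 0:
            raise ValueError("trial_duration must be positive")
        if self.iti_range[0] > self.iti_range[1] or self.iti_range[0] < 0:
            raise ValueError("iti_range must satisfy 0 <= low <= high")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition in TOUCH_CONDITIONS and not (5.0 <= self.touch_distance <= 50.0):
            raise ValueError("touch_distance must lie in [5, 50] cm for touch conditions")
        if self.perturbation_duration <= 0:
            raise ValueError("perturbation_duration must be positive")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.run_bout_rate < 0 or self.run_bout_duration <= 0:
            raise ValueError("bout parameters must be non-negative / positive")
        if self.run_bout_rate > 0 and 60.0 / self.run_bout_rate <= self.run_bout_duration:
            raise ValueError("run_bout_rate too high for run_bout_duration (occupancy >= 1)")

    @property
    def perturbations_enabled(self) -> bool:
        if self.include_perturbations is None:
            return self.condition in ("perturbed_closed_loop", "open_loop")
        return self.include_perturbations

    @property
    def run_occupancy(self) -> float:
        """Analytic fraction of time in the running state."""
        return self.run_bout_rate * self.run_bout_duration / 60.0


@dataclass
class NeuronSpec:
    """Generative parameters of one synthetic neuron.

    The firing rate is a sum of a baseline, a running term (state gain or a
    Gaussian speed-tuning curve), a touch term (sustained, or a boxcar of
    ``touch_duration`` seconds after contact onset), a run-x-touch
    interaction, and an optional perturbation term.  Negative sums are
    clipped at zero (suppressed neurons need negative gains); the clipped
    fraction is recorded and warned about.
    """

    category: str = "rest"                # rest | run | touch | integrative
    baseline_rate: float = 2.0            # Hz
    run_gain: float = 0.0                 # Hz while running (or peak of tuning)
    touch_gain: float = 0.0               # Hz while in contact
    interaction_gain: float = 0.0         # Hz while running AND in contact
    perturbation_gain: float = 0.0        # Hz during a texture halt
    speed_tuning: tuple[float, float, float] | None = None  # (s_max, sig-, sig+), cm/s & (cm/s)^2
    touch_duration: float | None = None   # s; None = sustained during contact
    kernel_amplitude: float = 0.095       # fractional dF/F per action potential
    kernel_tau: float = 0.35              # s decay time constant
    noise_sd: float = 0.02                # dF/F units, additive Gaussian
    f0: float = 100.0                     # raw baseline fluorescence
    background: float = 10.0              # raw background fluorescence

    def __post_init__(self):
        if min(self.kernel_amplitude, self.kernel_tau) <= 0:
            raise ValueError("kernel amplitude and tau must be positive")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")

    @classmethod
    def make(cls, category: str, rng: np.random.Generator, **overrides) -> "NeuronSpec":
        """A neuron of the given functional category with default gains and
        kernel parameters drawn from the published single-AP ranges."""
        gains = {
            "rest": dict(baseline_rate=5.0, run_gain=-3.0, touch_gain=-3.0, interaction_gain=2.0),
            "run": dict(baseline_rate=1.0, run_gain=6.0),
            "touch": dict(baseline_rate=1.0, touch_gain=6.0),
            "integrative": dict(baseline_rate=1.0, run_gain=1.0, touch_gain=1.0,
                                interaction_gain=6.0),
            "noise": dict(baseline_rate=2.0),
        }[category]
        params = dict(
            category=category if category != "noise" else "rest",
            kernel_amplitude=rng.uniform(0.08, 0.11),
            kernel_tau=rng.uniform(0.3, 0.4),
            **gains,
        )
        params.update(overrides)
        return cls(**params)


# --------------------------------------------------------------------------
# behavior generation
# --------------------------------------------------------------------------

def _snap(t: float) -> float:
    return round(t / _GRID) * _GRID


def _alternating_bouts(rng, total_s, bout_rate_per_min, mean_on_s, min_bout_s=0.5):
    """Exponential rest/run alternation; returns list of (start, end) on-bouts."""
    if bout_rate_per_min <= 0:
        return []
    mean_off = 60.0 / bout_rate_per_min - mean_on_s
    bouts = []
    t = 0.0
    while t < total_s:
        t += max(min_bout_s, rng.exponential(mean_off))
        if t >= total_s:
            break
        dur = max(min_bout_s, rng.exponential(mean_on_s))
        end = min(t + dur, total_s)
        bouts.append((_snap(t), _snap(end)))
        t = end
    return [(s, e) for s, e in bouts if e - s >= min_bout_s]


def _rasterize(intervals, n, rate_hz):
    out = np.zeros(n, dtype=bool)
    for s, e in intervals:
        out[int(round(s * rate_hz)): int(round(e * rate_hz))] = True
    return out


def _speed_trace(rng, run_bouts, n40, mean_sd):
    """Run speed at 40 Hz: per-bout target speed with 0.4-s ramps and slow
    within-bout modulation, plus small encoder noise."""
    speed = np.zeros(n40)
    t40 = np.arange(n40) / SPEED_RATE_HZ
    for s, e in run_bouts:
        i0, i1 = int(round(s * SPEED_RATE_HZ)), int(round(e * SPEED_RATE_HZ))
        target = max(2.0, rng.normal(*mean_sd))
        seg_t = t40[i0:i1]
        ramp = np.minimum(1.0, np.minimum(seg_t - s, e - seg_t) / 0.4)
        wobble = 1.0 + 0.1 * np.sin(2 * np.pi * 0.3 * (seg_t - s) + rng.uniform(0, 2 * np.pi))
        speed[i0:i1] = target * np.clip(ramp, 0, 1) * wobble
    speed += rng.normal(0, 0.02, n40)
    return np.clip(speed, 0, None)


def _whisker_trace(rng, whisk_200, whisk_std_deg=8.0):
    """Mean whisker angle at 200 Hz: 5-15 Hz band-limited oscillation during
    whisking (sliding-window std well above 2.5 deg), low-amplitude jitter
    otherwise."""
    b, a = butter(2, [5.0 / (WHISKER_RATE_HZ / 2), 15.0 / (WHISKER_RATE_HZ / 2)], "bandpass")
    n200 = len(whisk_200)
    osc = filtfilt(b, a, rng.standard_normal(n200))
    osc /= max(osc.std(), 1e-12)
    envelope = np.convolve(whisk_200.astype(float), np.ones(21) / 21, mode="same")
    return whisk_std_deg * envelope * osc + rng.normal(0, 0.2, n200)


def generate_behavior(config: BehaviorConfig) -> SessionBundle:
    """Generate all behavior/stimulus streams of one session (no fluorescence).

    Running bouts always coincide with whisking (whisking is dilated 1 s
    around every run bout, so running-without-whisking has zero occupancy in
    the ground truth).  Touch logic per condition: in closed loop the texture
    moves in once the within-trial run distance reaches ``touch_distance``
    and then rotates at the run speed; in open loop it rotates at an
    independently generated speed; in no-touch the stage and texture move
    identically to closed loop but contact never happens (sound control).
    Perturbations halt the texture for ``perturbation_duration`` seconds once
    per contact period at a uniformly random admissible time.
    """
    if config.perturbations_enabled and config.condition == "no_touch":
        raise ValueError("perturbations require a touch condition, not no_touch")
    rng = np.random.default_rng(config.rng_seed)

    # trial schedule
    lead_in = 2.0
    trials = []
    t = lead_in
    for _ in range(config.n_trials):
        start = _snap(t)
        end = _snap(start + config.trial_duration)
        trials.append((start, end))
        t = end + _snap(rng.uniform(*config.iti_range))
    total = trials[-1][1]
    n10 = int(round(total * IMAGING_RATE_HZ))
    n40, n200 = n10 * 4, n10 * 20

    # locomotion and whisking bouts
    run_bouts = _alternating_bouts(rng, total, config.run_bout_rate, config.run_bout_duration)
    whisk_intervals = [(max(0.0, s - 1.0), min(total, e + 1.0)) for s, e in run_bouts]
    # extra whisking during rest gaps
    gaps, prev = [], 0.0
    for s, e in whisk_intervals:
        if s - prev > 2.0:
            gaps.append((prev, s))
        prev = max(prev, e)
    if total - prev > 2.0:
        gaps.append((prev, total))
    for gs, ge in gaps:
        if rng.uniform() < config.rest_whisk_prob:
            dur = float(np.clip(rng.exponential(3.0), 0.8, ge - gs - 0.4))
            start = rng.uniform(gs + 0.2, max(gs + 0.2, ge - dur - 0.2))
            whisk_intervals.append((_snap(start), _snap(start + dur)))
    whisk_intervals.sort()

    run_10 = _rasterize(run_bouts, n10, IMAGING_RATE_HZ)
    whisk_10 = _rasterize(whisk_intervals, n10, IMAGING_RATE_HZ)
    whisk_200 = _rasterize(whisk_intervals, n200, WHISKER_RATE_HZ)

    run_speed = _speed_trace(rng, run_bouts, n40, config.speed_profile)
    speed_10 = run_speed.reshape(n10, 4).mean(axis=1)
    whisker_angle = _whisker_trace(rng, whisk_200)

    # touch / stage / perturbation logic per trial
    contact = np.zeros(n10, dtype=bool)
    stage_moving = np.zeros(n10, dtype=bool)
    perturb = np.zeros(n10, dtype=bool)
    texture_speed = np.zeros(n10)
    stage_travel, touch_latency = 0.3, 0.2
    touch_onset_times, perturbation_times = [], []

    if config.condition == "open_loop":
        alt = np.random.default_rng(rng.integers(2**31))
        alt_bouts = _alternating_bouts(alt, total, config.run_bout_rate, config.run_bout_duration)
        open_speed_40 = _speed_trace(alt, alt_bouts, n40, config.speed_profile)
        drive_10 = open_speed_40.reshape(n10, 4).mean(axis=1)
    else:
        drive_10 = speed_10

    for (ts, te) in trials:
        if config.condition == "open_loop":
            # stage-in time decoupled from locomotion so touches happen
            # during running and during resting alike
            t_stage = _snap(rng.uniform(ts + 2.0, te - 6.0))
        else:
            i0, i1 = int(round(ts * SPEED_RATE_HZ)), int(round(te * SPEED_RATE_HZ))
            dist = np.cumsum(run_speed[i0:i1]) / SPEED_RATE_HZ
            hit = np.nonzero(dist >= config.touch_distance)[0]
            if len(hit) == 0:
                continue
            t_stage = _snap(ts + hit[0] / SPEED_RATE_HZ)
        if te - t_stage < 2.0:            # too late in the trial to matter
            continue
        stage_moving[int(round(t_stage * 10)): int(round(_snap(t_stage + stage_travel) * 10))] = True
        c0 = _snap(t_stage + touch_latency)
        j0, j1 = int(round(c0 * 10)), int(round(te * 10))
        touch_onset_times.append(t_stage)
        if config.condition != "no_touch":
            contact[j0:j1] = True
        texture_speed[j0:j1] = drive_10[j0:j1]
        if config.perturbations_enabled and (te - c0) > config.perturbation_duration + 1.0:
            p0 = _snap(rng.uniform(c0 + 0.5, te - config.perturbation_duration - 0.1))
            k0, k1 = int(round(p0 * 10)), int(round((p0 + config.perturbation_duration) * 10))
            perturb[k0:k1] = True
            texture_speed[k0:k1] = 0.0
            perturbation_times.append(p0)

    ground_truth = {
        "config": dataclasses.asdict(config),
        "run_bouts": run_bouts,
        "whisk_intervals": whisk_intervals,
        "running_10hz": run_10.astype(int),
        "whisking_10hz": whisk_10.astype(int),
        "speed_10hz": speed_10,
        "touch_onset_times": touch_onset_times,
        "perturbation_times": perturbation_times,
    }
    bundle = SessionBundle(
        run_speed=run_speed,
        whisker_angle=whisker_angle,
        texture_speed=texture_speed,
        contact_flag=contact.astype(int),
        stage_moving_flag=stage_moving.astype(int),
        perturbation_flag=perturb.astype(int),
        trial_intervals=trials,
        meta={"condition": config.condition, "layer": config.layer, "seed": config.rng_seed},
        ground_truth=ground_truth,
    )
    bundle.validate()
    return bundle


# --------------------------------------------------------------------------
# fluorescence generation
# --------------------------------------------------------------------------

def calcium_kernel(amplitude: float, tau: float, dt: float = 1.0 / IMAGING_RATE_HZ) -> np.ndarray:
    """Frame-bin-integrated single-AP kernel.

    Each imaging frame measures the average fluorescence over its exposure,
    so the exponential A*exp(-t/tau) is integrated over successive dt bins.
    The kernel sum is then exactly A*tau/dt, which makes the steady-state
    dF/F of a constant rate r equal r*A*tau with no discretization bias.
    """
    n = max(1, int(np.ceil(10.0 * tau / dt)))
    j = np.arange(n)
    return amplitude * (tau / dt) * (1.0 - np.exp(-dt / tau)) * np.exp(-j * dt / tau)


def _neuron_rate(spec: NeuronSpec, gt: dict) -> tuple[np.ndarray, float]:
    running = np.asarray(gt["running_10hz"], dtype=float)
    contact = np.asarray(gt["contact_10hz"], dtype=float)
    perturb = np.asarray(gt["perturbation_10hz"], dtype=float)
    speed = np.asarray(gt["speed_10hz"], dtype=float)
    lam = np.full(len(running), spec.baseline_rate)
    if spec.speed_tuning is not None:
        s_max, sig_minus, sig_plus = spec.speed_tuning
        sig = np.where(speed < s_max, sig_minus, sig_plus)
        lam += spec.run_gain * np.exp(-((speed - s_max) ** 2) / sig)
    else:
        lam += spec.run_gain * running
    if spec.touch_duration is None:
        lam += spec.touch_gain * contact
    else:
        onsets = np.nonzero(np.diff(np.concatenate([[0], contact])) > 0)[0]
        box = np.zeros_like(contact)
        w = int(round(spec.touch_duration * IMAGING_RATE_HZ))
        for i in onsets:
            box[i: i + w] = 1.0
        lam += spec.touch_gain * box * contact
    lam += spec.interaction_gain * running * contact
    lam += spec.perturbation_gain * perturb
    clipped = float(np.mean(lam < 0))
    return np.clip(lam, 0.0, None), clipped


def generate_fluorescence(
    behavior: SessionBundle, specs: list[NeuronSpec], rng_seed: int = 0
) -> SessionBundle:
    """Attach raw fluorescence generated forward from the per-neuron model.

    Rate -> Poisson spikes per frame -> linear convolution with the
    bin-integrated calcium kernel -> additive Gaussian noise -> raw
    F = f0 * (1 + dF/F) + background.  Ground truth (specs, rates, spike
    counts, clipped-rate fraction) is recorded in the bundle.
    """
    if not specs:
        raise ValueError("need at least one NeuronSpec")
    if behavior.ground_truth is None:
        raise ValueError("behavior bundle lacks generative ground truth")
    gt = dict(behavior.ground_truth)
    gt["contact_10hz"] = np.asarray(behavior.contact_flag)
    gt["perturbation_10hz"] = np.asarray(behavior.perturbation_flag)
    n10 = behavior.n_frames
    dt = 1.0 / IMAGING_RATE_HZ
    streams = np.random.SeedSequence(rng_seed).spawn(len(specs))
    fluo = np.empty((len(specs), n10))
    neuron_truth = []
    for i, (spec, ss) in enumerate(zip(specs, streams)):
        rng = np.random.default_rng(ss)
        lam, clipped = _neuron_rate(spec, gt)
        if clipped > 0:
            warnings.warn(
                f"neuron {i}: rate clipped at zero on {clipped:.1%} of frames",
                stacklevel=2,
            )
        spikes = rng.poisson(lam * dt)
        kern = calcium_kernel(spec.kernel_amplitude, spec.kernel_tau, dt)
        dff = np.convolve(spikes.astype(float), kern)[:n10]
        if spec.noise_sd > 0:
            dff = dff + rng.normal(0, spec.noise_sd, n10)
        fluo[i] = spec.f0 * (1.0 + dff) + spec.background
        neuron_truth.append(
            {
                "spec": dataclasses.asdict(spec),
                "mean_rate_hz": float(lam.mean()),
                "n_spikes": int(spikes.sum()),
                "clipped_fraction": clipped,
            }
        )
    out = dataclasses.replace(behavior, fluo=fluo)
    out.ground_truth = {**behavior.ground_truth, "neurons": neuron_truth,
                        "fluo_seed": rng_seed}
    out.validate()
    return out


def make_session(
    behavior_config: BehaviorConfig,
    specs: list[NeuronSpec],
    fluo_seed: int | None = None,
) -> SessionBundle:
    """Convenience: behavior + fluorescence in one call."""
    behavior = generate_behavior(behavior_config)
    seed = behavior_config.rng_seed + 1 if fluo_seed is None else fluo_seed
    return generate_fluorescence(behavior, specs, seed)
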