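"""Behavioral-state segmentation and event detection at the imaging rate.

Whisking: the sliding 51-point standard deviation of the mean whisker angle
(computed at the native 200-Hz camera rate, whose 0.255-s window spans the
5-15 Hz whisking band) is downsampled to 10 Hz and thresholded at 2.5
degrees.  The same windowed std, at 10 Hz, serves as the whisking envelope
for the encoding model.

Running: the 40-Hz encoder trace is smoothed with a 1-s Gaussian filter,
downsampled to 10 Hz, smoothed again with a 1.1-s first-order
Savitzky-Golay filter, and thresholded at |speed| > 0.8 cm/s.

Onsets: a 0->1 transition preceded by at least 400 ms off and followed by at
least 400 ms on.  Whisking-onset segments end when whisking stops or running
starts; running-onset segments end at the running offset.  Touch onsets are
the times the linear stage starts moving toward the whiskers; stage motions
never followed by contact are kept separately as sound-control events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter

from .config import IMAGING_RATE_HZ, SPEED_RATE_HZ, WHISKER_RATE_HZ, PipelineConfig

logger = logging.getLogger(__name__)

STATES = ("rest_nowhisk", "rest_whisk", "run_nowhisk", "run_whisk")


@dataclass
class StateTimeline:
    """Per-frame behavioral state at the imaging rate."""

    whisking: np.ndarray            # binary
    running: np.ndarray             # binary
    speed: np.ndarray               # smoothed run speed, cm/s
    whisk_envelope: np.ndarray      # sliding-window angle std, degrees
    touch: np.ndarray               # binary contact
    perturbation: np.ndarray        # binary texture halt

    def __post_init__(self):
        n = {len(getattr(self, f)) for f in
             ("whisking", "running", "speed", "whisk_envelope", "touch", "perturbation")}
        if len(n) != 1:
            raise ValueError("all state streams must share one length")

    @property
    def n_frames(self) -> int:
        return len(self.whisking)

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / IMAGING_RATE_HZ

    @property
    def state(self) -> np.ndarray:
        """Four-way run x whisk label per frame."""
        idx = 2 * self.running.astype(int) + self.whisking.astype(int)
        return np.array(STATES, dtype=object)[idx]

    def occupancy(self) -> dict[str, float]:
        labels, counts = np.unique(self.state, return_counts=True)
        occ = {s: 0.0 for s in STATES}
        occ.update(dict(zip(labels, counts / self.n_frames)))
        return occ

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.frame_times,
                "whisking": self.whisking.astype(int),
                "running": self.running.astype(int),
                "state": self.state,
                "speed": self.speed,
                "whisk_envelope": self.whisk_envelope,
                "touch": self.touch.astype(int),
                "perturbation": self.perturbation.astype(int),
            }
        )


@dataclass
class EventSet:
    """Onset times with per-event truncation and speed context."""

    kind: str
    times: np.ndarray                       # onset, s
    ends: np.ndarray                        # segment end (truncation), s
    context_speed: np.ndarray | None = None  # mean run speed in window, cm/s

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ends = np.asarray(self.ends, dtype=float)
        if len(self.times) != len(self.ends):
            raise ValueError("times and ends differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.ends < self.times):
            raise ValueError("segment end before onset")

    def __len__(self) -> int:
        return len(self.times)

    def subset(self, mask: np.ndarray) -> "EventSet":
        return EventSet(
            self.kind,
            self.times[mask],
            self.ends[mask],
            None if self.context_speed is None else self.context_speed[mask],
        )


# --------------------------------------------------------------------------
# state detection
# --------------------------------------------------------------------------

def whisk_envelope_10hz(whisker_angle: np.ndarray, window: int = 51) -> np.ndarray:
    """Sliding-window std of the whisker angle, downsampled to 10 Hz."""
    angle = pd.Series(np.asarray(whisker_angle, dtype=float))
    std = angle.rolling(window, center=True, min_periods=2).std(ddof=0)
    std = std.bfill().ffill().to_numpy()
    step = int(round(WHISKER_RATE_HZ / IMAGING_RATE_HZ))
    return std[::step]


def detect_whisking(
    whisker_angle: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary whisking at 10 Hz plus the whisking envelope (windowed std)."""
    config = config or PipelineConfig()
    env = whisk_envelope_10hz(whisker_angle, config.whisk_std_window)
    return env > config.whisk_std_threshold_deg, env


def detect_running(
    run_speed: np.ndarray, config: PipelineConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary running at 10 Hz plus the two-stage-smoothed speed.

    The 1-s Gaussian is applied as a kernel of 1-s full width at half
    maximum (sigma ~ 0.42 s) at 40 Hz before downsampling.
    """
    config = config or PipelineConfig()
    sigma_samples = config.run_gauss_fwhm_s / 2.355 * SPEED_RATE_HZ
    smooth40 = gaussian_filter1d(np.asarray(run_speed, dtype=float), sigma_samples)
    step = int(round(SPEED_RATE_HZ / IMAGING_RATE_HZ))
    speed10 = smooth40[::step]
    win = int(round(config.run_savgol_window_s * IMAGING_RATE_HZ))
    win += (win + 1) % 2  # Savitzky-Golay needs an odd window
    speed10 = savgol_filter(speed10, win, 1, mode="interp")
    return np.abs(speed10) > config.run_threshold_cms, speed10


def assign_states(
    whisking: np.ndarray,
    running: np.ndarray,
    speed: np.ndarray | None = None,
    whisk_envelope: np.ndarray | None = None,
    touch: np.ndarray | None = None,
    perturbation: np.ndarray | None = None,
) -> StateTimeline:
    whisking = np.asarray(whisking, dtype=bool)
    running = np.asarray(running, dtype=bool)
    if len(whisking) != len(running):
        raise ValueError("whisking and running differ in length")
    n = len(whisking)
    z = np.zeros(n)
    return StateTimeline(
        whisking=whisking,
        running=running,
        speed=z if speed is None else np.asarray(speed, dtype=float),
        whisk_envelope=z if whisk_envelope is None else np.asarray(whisk_envelope, dtype=float),
        touch=np.zeros(n, bool) if touch is None else np.asarray(touch, dtype=bool),
        perturbation=np.zeros(n, bool) if perturbation is None else np.asarray(perturbation, dtype=bool),
    )


# --------------------------------------------------------------------------
# event detection
# --------------------------------------------------------------------------

def detect_onsets(
    binary: np.ndarray,
    kind: str = "onset",
    min_off_s: float = 0.4,
    min_on_s: float = 0.4,
    truncate_at: np.ndarray | None = None,
    frame_rate: float = IMAGING_RATE_HZ,
) -> EventSet:
    """Onsets of a binary state: >= min_off off, then >= min_on on.

    Each event's segment runs until the state turns off again, or — when a
    second binary vector is given (running, for whisking onsets) — until
    that vector turns on, whichever comes first.
    """
    b = np.asarray(binary).astype(bool).astype(int)
    n_off = int(round(min_off_s * frame_rate))
    n_on = int(round(min_on_s * frame_rate))
    n = len(b)
    times, ends = [], []
    rising = np.nonzero(np.diff(b) == 1)[0] + 1
    for i in rising:
        if i < n_off or i + n_on > n:
            continue
        if b[i - n_off:i].any() or not b[i:i + n_on].all():
            continue
        off_after = np.nonzero(b[i:] == 0)[0]
        end = i + off_after[0] if len(off_after) else n
        if truncate_at is not None:
            tr = np.asarray(truncate_at).astype(bool)
            tr_after = np.nonzero(tr[i:])[0]
            if len(tr_after):
                end = min(end, i + tr_after[0])
        times.append(i / frame_rate)
        ends.append(end / frame_rate)
    return EventSet(kind, np.array(times), np.array(ends))


def touch_onsets(
    stage_moving_flag: np.ndarray,
    contact_flag: np.ndarray,
    frame_rate: float = IMAGING_RATE_HZ,
    contact_lookahead_s: float = 2.0,
) -> tuple[EventSet, EventSet]:
    """Touch onsets at stage-motion starts; contactless motions -> controls.

    Returns (touch_events, sound_control_events).  Touch segments end when
    the contact period ends; control segments get a fixed 4-s window.
    """
    stage = np.asarray(stage_moving_flag).astype(bool).astype(int)
    contact = np.asarray(contact_flag).astype(bool).astype(int)
    n = len(stage)
    look = int(round(contact_lookahead_s * frame_rate))
    rising = np.nonzero(np.diff(np.concatenate([[0], stage])) == 1)[0]
    t_times, t_ends, c_times, c_ends = [], [], [], []
    for i in rising:
        window = contact[i: i + look]
        hit = np.nonzero(window)[0]
        if len(hit):
            j = i + hit[0]
            off = np.nonzero(contact[j:] == 0)[0]
            end = j + off[0] if len(off) else n
            t_times.append(i / frame_rate)
            t_ends.append(end / frame_rate)
        else:
            c_times.append(i / frame_rate)
            c_ends.append(min(n, i + int(4.0 * frame_rate)) / frame_rate)
    return (
        EventSet("touch_onset", np.array(t_times), np.array(t_ends)),
        EventSet("sound_control", np.array(c_times), np.array(c_ends)),
    )


def _event_context_speed(
    events: EventSet,
    speed: np.ndarray,
    window: tuple[float, float],
    frame_rate: float,
) -> tuple[EventSet, np.ndarray]:
    """Attach mean speed in `window` around each onset; drop events whose
    window exceeds the recording."""
    n = len(speed)
    keep, context = [], []
    for k, t in enumerate(events.times):
        i0 = int(round((t + window[0]) * frame_rate))
        i1 = int(round((t + window[1]) * frame_rate))
        if i0 < 0 or i1 > n:
            logger.info("event at %.1f s dropped: context window exceeds recording", t)
            continue
        keep.append(k)
        context.append(float(np.mean(speed[i0:i1])))
    mask = np.zeros(len(events), dtype=bool)
    mask[keep] = True
    out = events.subset(mask)
    out.context_speed = np.array(context)
    return out, np.array(context)


def split_touch_events(
    events: EventSet,
    speed: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[EventSet, EventSet]:
    """Touch-during-running (mean speed > 2 cm/s in the -1..+4 s window) vs
    touch-during-resting (< 1 cm/s); the 1-2 cm/s band belongs to neither."""
    config = config or PipelineConfig()
    ev, ctx = _event_context_speed(events, speed, config.touch_context_window, IMAGING_RATE_HZ)
    running = ev.subset(ctx > config.touch_run_speed_cms)
    resting = ev.subset(ctx < config.touch_rest_speed_cms)
    return running, resting


def select_perturbations(
    perturbation_flag: np.ndarray,
    speed: np.ndarray,
    config: PipelineConfig | None = None,
) -> tuple[EventSet, EventSet]:
    """Perturbation onsets during running (mean window speed > 2 cm/s) and,
    for open-loop analyses, the resting subset (< 1 cm/s)."""
    config = config or PipelineConfig()
    flag = np.asarray(perturbation_flag).astype(bool).astype(int)
    rising = np.nonzero(np.diff(np.concatenate([[0], flag])) == 1)[0]
    times, ends = [], []
    for i in rising:
        off = np.nonzero(flag[i:] == 0)[0]
        end = i + off[0] if len(off) else len(flag)
        times.append(i / IMAGING_RATE_HZ)
        ends.append(end / IMAGING_RATE_HZ)
    events = EventSet("perturbation_onset", np.array(times), np.array(ends))
    ev, ctx = _event_context_speed(events, speed, config.touch_context_window, IMAGING_RATE_HZ)
    running = ev.subset(ctx > config.perturb_run_speed_cms)
    resting = ev.subset(ctx < config.touch_rest_speed_cms)
    return running, resting


def segment_session(bundle, config: PipelineConfig | None = None) -> StateTimeline:
    """Full per-frame StateTimeline for one session bundle."""
    config = config or PipelineConfig()
    whisking, env = detect_whisking(bundle.whisker_angle, config)
    running, speed = detect_running(bundle.run_speed, config)
    n = bundle.n_frames
    return StateTimeline(
        whisking=whisking[:n],
        running=running[:n],
        speed=speed[:n],
        whisk_envelope=env[:n],
        touch=np.asarray(bundle.contact_flag, dtype=bool),
        perturbation=np.asarray(bundle.perturbation_flag, dtype=bool),
    )
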