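"""Event-aligned averaging and per-neuron response metrics.

Onset-aligned dF/F segments run from 2 s before a whisking/running onset
until the event's truncation time (whisking stopped / running started or
stopped); the per-lag average over events is smoothed with a 500-ms
first-order Savitzky-Golay filter.  Modulation for whisking, running and
touch is the post-window maximum minus the pre-window mean; perturbation
modulation P is the difference of mean dF/F between the +0.3..+2 s and
-1..-0.3 s windows.  A neuron is responsive when its modulation exceeds
twice the baseline noise sigma (perturbation: two-sided, up P > 2 sigma /
down P < -2 sigma).

Touch responses use the published analysis windows (pre -1..-0.3 s, early E
0.3..1.3 s, late L 2..3 s): E is the peak of the pre-subtracted average in
the early window, L the mean in the late window, and percent suppression
100 * (E - L) / E for neurons with E > 0.

The modulation index between two condition means is (a - b) / (a + b); the
whisking index compares rest/whisk against rest/no-whisk frames with all
running excluded, the running index compares running against resting frames
regardless of whisking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .config import IMAGING_RATE_HZ, PipelineConfig
from .segmentation import EventSet, StateTimeline

logger = logging.getLogger(__name__)


@dataclass
class AlignedResponse:
    kind: str
    lags: np.ndarray            # s, pre..post
    mean: np.ndarray            # trial-averaged, Savitzky-Golay smoothed
    n_per_lag: np.ndarray       # events contributing at each lag
    n_events: int

    @property
    def empty(self) -> bool:
        return self.n_events == 0

    def window_slice(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        return (self.lags >= lo) & (self.lags <= hi)


@dataclass
class NeuronResponse:
    whisk_mi: float = np.nan
    run_mi: float = np.nan
    whisk_mod: float = np.nan
    run_mod: float = np.nan
    touch_E: float = np.nan
    touch_L: float = np.nan
    suppression_pct: float = np.nan
    perturbation_P: float = np.nan
    responsive_whisk: bool = False
    responsive_run: bool = False
    responsive_touch: bool = False
    up_modulated: bool = False
    down_modulated: bool = False


def align_and_average(
    dff: np.ndarray,
    events: EventSet,
    pre_s: float = 2.0,
    frame_rate: float = IMAGING_RATE_HZ,
    smooth_window_s: float = 0.5,
) -> AlignedResponse:
    """Average event-aligned dF/F with per-event truncation.

    Events lacking a full pre window inside the trace are skipped; each
    segment contributes lags only up to its own truncation time, so the
    per-lag average is over however many events are still 'alive' there.
    """
    dff = np.asarray(dff, dtype=float)
    n = len(dff)
    n_pre = int(round(pre_s * frame_rate))
    segments = []
    for t, end in zip(events.times, events.ends):
        i = int(round(t * frame_rate))
        j = min(int(round(end * frame_rate)), n)
        if i - n_pre < 0 or i >= n:
            continue
        segments.append(dff[i - n_pre: j])
    if not segments:
        logger.info("no usable %s events for alignment", events.kind)
        return AlignedResponse(events.kind, np.array([]), np.array([]), np.array([]), 0)
    max_len = max(len(s) for s in segments)
    stack = np.full((len(segments), max_len), np.nan)
    for k, s in enumerate(segments):
        stack[k, : len(s)] = s
    n_per_lag = np.sum(~np.isnan(stack), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    keep = n_per_lag > 0
    mean, n_per_lag = mean[keep], n_per_lag[keep]
    win = int(round(smooth_window_s * frame_rate))
    win += (win + 1) % 2
    if win >= 3 and len(mean) >= win:
        # NaNs (excluded frames) would poison the filter; interpolate across them
        if np.isnan(mean).any():
            idx = np.arange(len(mean))
            ok = ~np.isnan(mean)
            mean = np.interp(idx, idx[ok], mean[ok]) if ok.any() else mean
        mean = savgol_filter(mean, win, 1, mode="interp")
    lags = (np.arange(len(mean)) - n_pre) / frame_rate
    return AlignedResponse(events.kind, lags, mean, n_per_lag, len(segments))


def modulation_index(mean_a: float, mean_b: float) -> float:
    """(a - b) / (a + b); undefined (NaN) when a + b <= 0."""
    denom = mean_a + mean_b
    if not np.isfinite(denom) or denom <= 0:
        logger.info("modulation index undefined for means (%.4g, %.4g)", mean_a, mean_b)
        return np.nan
    return (mean_a - mean_b) / denom


def state_means(
    dff: np.ndarray, states: StateTimeline, restriction: str = "exclude_running"
) -> dict[str, float]:
    """Mean dF/F per behavioral condition.

    restriction='exclude_running': rest/whisk vs rest/no-whisk means over
    non-running frames only (whisking index).  restriction='all': running vs
    resting means regardless of whisking (running index).
    """
    dff = np.asarray(dff, dtype=float)
    if len(dff) != states.n_frames:
        raise ValueError("dff and state timeline differ in length")

    def _mean(mask):
        if not mask.any() or np.all(np.isnan(dff[mask])):
            return np.nan
        return float(np.nanmean(dff[mask]))

    if restriction == "exclude_running":
        rest = ~states.running
        return {
            "rest_whisk": _mean(rest & states.whisking),
            "rest_nowhisk": _mean(rest & ~states.whisking),
        }
    if restriction == "all":
        return {"run": _mean(states.running), "rest": _mean(~states.running)}
    raise ValueError(f"unknown restriction {restriction!r}")


def event_modulation(
    resp: AlignedResponse,
    sigma: float,
    mode: str = "max_post",
    config: PipelineConfig | None = None,
) -> tuple[float, bool | tuple[bool, bool]]:
    """Modulation value and responsiveness of an aligned average.

    mode='max_post' (whisking/running/touch onsets): max of the post-onset
    average minus the pre-onset mean; responsive when > 2 sigma.
    mode='mean_post' (perturbation): mean(+0.3..+2 s) - mean(-1..-0.3 s);
    returns (P, (up, down)) with the two-sided 2-sigma criterion.
    """
    config = config or PipelineConfig()
    k = config.responsive_sigma_factor
    if resp.empty:
        return np.nan, (False, False) if mode == "mean_post" else False
    if mode == "max_post":
        pre = resp.mean[resp.lags < 0]
        post = resp.mean[resp.lags >= 0]
        if len(post) == 0 or len(pre) == 0:
            return np.nan, False
        mod = float(np.nanmax(post) - np.nanmean(pre))
        return mod, bool(mod > k * sigma)
    if mode == "mean_post":
        pre_m = resp.window_slice(config.touch_pre_window)
        post_m = resp.window_slice(config.perturb_post_window)
        if not pre_m.any() or not post_m.any():
            return np.nan, (False, False)
        p = float(np.nanmean(resp.mean[post_m]) - np.nanmean(resp.mean[pre_m]))
        return p, (bool(p > k * sigma), bool(p < -k * sigma))
    raise ValueError(f"unknown mode {mode!r}")


def touch_metrics(
    resp: AlignedResponse,
    sigma: float,
    config: PipelineConfig | None = None,
) -> tuple[float, float, float, bool]:
    """(E, L, suppression %, responsive) from a touch-aligned average.

    The pre-touch mean (-1..-0.3 s) is subtracted first; E is the peak in
    0.3..1.3 s, L the mean in 2..3 s, suppression 100*(E-L)/E for E > 0
    (undefined otherwise) and responsiveness E > 2 sigma.
    """
    config = config or PipelineConfig()
    if resp.empty:
        return np.nan, np.nan, np.nan, False
    pre_m = resp.window_slice(config.touch_pre_window)
    e_m = resp.window_slice(config.touch_early_window)
    l_m = resp.window_slice(config.touch_late_window)
    if not (pre_m.any() and e_m.any() and l_m.any()):
        return np.nan, np.nan, np.nan, False
    centered = resp.mean - np.nanmean(resp.mean[pre_m])
    e = float(np.nanmax(centered[e_m]))
    late = float(np.nanmean(centered[l_m]))
    supp = 100.0 * (e - late) / e if e > 0 else np.nan
    return e, late, supp, bool(e > config.responsive_sigma_factor * sigma)


def neuron_response(
    dff: np.ndarray,
    sigma: float,
    states: StateTimeline,
    whisk_events: EventSet | None = None,
    run_events: EventSet | None = None,
    touch_events: EventSet | None = None,
    perturb_events: EventSet | None = None,
    config: PipelineConfig | None = None,
) -> NeuronResponse:
    """All response metrics of one neuron in one session."""
    config = config or PipelineConfig()
    out = NeuronResponse()
    wm = state_means(dff, states, "exclude_running")
    out.whisk_mi = modulation_index(wm["rest_whisk"], wm["rest_nowhisk"])
    rm = state_means(dff, states, "all")
    out.run_mi = modulation_index(rm["run"], rm["rest"])
    pre = config.onset_pre_s
    if whisk_events is not None and len(whisk_events):
        resp = align_and_average(dff, whisk_events, pre, smooth_window_s=config.event_smooth_window_s)
        out.whisk_mod, out.responsive_whisk = event_modulation(resp, sigma, "max_post", config)
    if run_events is not None and len(run_events):
        resp = align_and_average(dff, run_events, pre, smooth_window_s=config.event_smooth_window_s)
        out.run_mod, out.responsive_run = event_modulation(resp, sigma, "max_post", config)
    if touch_events is not None and len(touch_events):
        resp = align_and_average(dff, touch_events, pre, smooth_window_s=config.event_smooth_window_s)
        out.touch_E, out.touch_L, out.suppression_pct, out.responsive_touch = touch_metrics(
            resp, sigma, config
        )
    if perturb_events is not None and len(perturb_events):
        resp = align_and_average(dff, perturb_events, pre, smooth_window_s=config.event_smooth_window_s)
        out.perturbation_P, (out.up_modulated, out.down_modulated) = event_modulation(
            resp, sigma, "mean_post", config
        )
    return out
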