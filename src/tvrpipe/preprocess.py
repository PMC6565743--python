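"""Raw fluorescence to dF/F, noise and SNR statistics, slice-trace utilities.

dF/F = (F - F0)/F0 with the background subtracted from F and F0 taken as the
1st percentile of the 51-point first-order Savitzky-Golay-smoothed trace
concatenated over all trials of a session.  Baseline noise sigma is the 1st
percentile, over all 5-s sliding windows, of the within-window standard
deviation; SNR is the 95th dF/F percentile divided by sigma.  A 50%
steady-state dF/F change maps to a firing-rate change of dff/(A*tau),
11-21 Hz over the single-AP kernel ranges A in [8, 11]% and tau in
[0.3, 0.4] s.

Also provides the in-vitro slice-trace helpers: photobleaching correction
(exponential fitted outside a -0.24/+1.44 s window around the transient
peak) and single-exponential decay-constant fits from the peak onward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .config import IMAGING_RATE_HZ

SAVGOL_BASELINE_WINDOW = 51   # frames
NOISE_WINDOW_S = 5.0


@dataclass
class TraceStats:
    f0: float       # baseline fluorescence, raw units
    sigma: float    # baseline noise, dF/F units
    snr: float      # dimensionless


@dataclass
class KernelFit:
    amplitude: float
    tau: float
    converged: bool = True
    bleach_params: tuple[float, float] | None = None  # (scale, rate 1/s)


def compute_dff(raw_trace: np.ndarray, background: float = 0.0) -> tuple[np.ndarray, float]:
    """Background-subtracted dF/F and the baseline F0.

    F0 is the 1st percentile of the Savitzky-Golay-smoothed (51 frames,
    order 1) background-subtracted trace; smoothing over a long window
    estimates the fluorescence of the neuron while it is not firing.
    """
    raw_trace = np.asarray(raw_trace, dtype=float)
    if len(raw_trace) < SAVGOL_BASELINE_WINDOW:
        raise ValueError(
            f"trace of {len(raw_trace)} frames is shorter than the "
            f"{SAVGOL_BASELINE_WINDOW}-frame baseline smoothing window"
        )
    f = raw_trace - background
    smoothed = savgol_filter(f, SAVGOL_BASELINE_WINDOW, 1, mode="interp")
    f0 = float(np.percentile(smoothed, 1))
    if f0 <= 0:
        raise ValueError(
            f"baseline F0={f0:.3g} is non-positive; background "
            f"{background:.3g} exceeds the trace floor"
        )
    return (f - f0) / f0, f0


def compute_baseline_noise(dff: np.ndarray, frame_rate: float = IMAGING_RATE_HZ) -> float:
    """Noise sigma: 1st percentile of the stride-1 5-s-window standard deviations."""
    dff = np.asarray(dff, dtype=float)
    w = int(round(NOISE_WINDOW_S * frame_rate))
    if len(dff) < w:
        raise ValueError(f"trace shorter than one {NOISE_WINDOW_S:.0f}-s window")
    windows = np.lib.stride_tricks.sliding_window_view(dff, w)
    stds = windows.std(axis=1, ddof=0)
    return float(np.percentile(stds, 1))


def compute_snr(dff: np.ndarray, sigma: float) -> float:
    if sigma <= 0:
        raise ValueError("sigma must be positive to define SNR")
    return float(np.percentile(np.asarray(dff, dtype=float), 95) / sigma)


def trace_stats(raw_trace: np.ndarray, background: float = 0.0,
                frame_rate: float = IMAGING_RATE_HZ) -> tuple[np.ndarray, TraceStats]:
    dff, f0 = compute_dff(raw_trace, background)
    sigma = compute_baseline_noise(dff, frame_rate)
    snr = compute_snr(dff, sigma) if sigma > 0 else np.nan
    return dff, TraceStats(f0=f0, sigma=sigma, snr=snr)


# --------------------------------------------------------------------------
# slice-trace utilities
# --------------------------------------------------------------------------

_EXCLUDE_PRE_S, _EXCLUDE_POST_S = 0.24, 1.44


def bleach_correct(
    slice_dff: np.ndarray,
    transient_peak_time: float,
    frame_rate: float,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Remove slow photobleaching from a slice dF/F trace.

    An exponential a*exp(-r*t) + c is fitted to all samples outside the
    ~1.7-s window (-0.24 to +1.44 s) around the transient peak; only the
    decaying component (fit minus its asymptote c) is subtracted, so a flat
    baseline passes through unchanged.
    """
    y = np.asarray(slice_dff, dtype=float)
    t = np.arange(len(y)) / frame_rate
    if not (t[0] <= transient_peak_time <= t[-1]):
        raise ValueError("transient peak time outside the trace")
    keep = (t < transient_peak_time - _EXCLUDE_PRE_S) | (t > transient_peak_time + _EXCLUDE_POST_S)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 samples outside the peak-exclusion window")

    def model(tt, a, r, c):
        return a * np.exp(-r * tt) + c

    a0 = y[keep][0] - y[keep][-1]
    if abs(a0) < 1e-12:
        a0 = 1e-3
    # the decay rate is weakly identified on short spans; multi-start on r
    best = None
    for r0 in (0.003, 0.01, 0.03, 0.1, 0.3, 1.0):
        try:
            popt, _ = curve_fit(
                model, t[keep], y[keep], p0=(a0, r0, y[keep][-1]),
                bounds=([-np.inf, 1e-4, -np.inf], [np.inf, 100.0, np.inf]),
                maxfev=20000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(t[keep], *popt) - y[keep]) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise RuntimeError("bleach fit failed to converge")
    a, r, c = best[1]
    # a near-constant exponential (r -> 0) is degenerate with the offset c;
    # when a constant explains the kept samples essentially as well, declare
    # the trace bleach-free rather than subtract an arbitrary split
    ss_exp = float(np.sum((model(t[keep], a, r, c) - y[keep]) ** 2))
    ss_const = float(np.sum((np.mean(y[keep]) - y[keep]) ** 2))
    if ss_const - ss_exp <= 0.01 * ss_const + 1e-12:
        return y.copy(), (0.0, 0.0)
    corrected = y - (model(t, a, r, c) - c)
    return corrected, (float(a), float(r))


def fit_decay_tau(transient: np.ndarray, frame_rate: float) -> KernelFit:
    """Single-exponential decay constant of a calcium transient, fitted from
    the peak sample onward by least squares."""
    y = np.asarray(transient, dtype=float)
    if len(y) < max(3, int(0.5 * frame_rate)):
        raise ValueError("decay segment shorter than 0.5 s")
    t = np.arange(len(y)) / frame_rate

    def model(tt, a, tau):
        return a * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, y, p0=(max(y[0], 1e-6), 0.3),
            bounds=([0, 1e-4], [np.inf, 60.0]), maxfev=20000,
        )
        return KernelFit(amplitude=float(popt[0]), tau=float(popt[1]), converged=True)
    except RuntimeError:
        return KernelFit(amplitude=np.nan, tau=np.nan, converged=False)


def rate_from_steady_state(dff_ss: float, amplitude: float, tau: float) -> float:
    """Firing rate implied by a steady-state dF/F under linear summation:
    rate = dff_ss / (A * tau)."""
    if amplitude <= 0 or tau <= 0:
        raise ValueError("kernel amplitude and tau must be positive")
    return dff_ss / (amplitude * tau)
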