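"""Plug-in mutual information between calcium signals and behavior.

Variables are discretized with uniform bins whose count follows the
Freedman-Diaconis-style rule k = (max(x) - min(x)) / (2.5 * iqr(x) *
n^(-1/3)) with n the samples per trial (k is computed per trial and the
session-wide median used).  Mutual information is the plug-in Shannon
estimate over the joint histogram, in bits:

    I(X;Y) = sum_xy p(x,y) * log2[ p(x,y) / (p(x) p(y)) ].

To absorb the indicator lag, I is scanned over calcium delays of +/-1000 ms
in 100-ms steps; the value at a 200-ms delay (where the scan peaks for
calcium-driven signals) is the one used in downstream comparisons, e.g. the
per-neuron difference between touch and no-touch periods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import IMAGING_RATE_HZ, PipelineConfig

logger = logging.getLogger(__name__)


@dataclass
class BinningSpec:
    k: int
    edges: np.ndarray   # k+1 uniform edges over [min, max]

    def digitize(self, x: np.ndarray) -> np.ndarray:
        return np.clip(np.digitize(np.asarray(x, dtype=float), self.edges[1:-1]), 0, self.k - 1)


def fd_bins(x: np.ndarray, n: int | None = None, coefficient: float = 2.5) -> BinningSpec:
    """Bin count per the modified Freedman-Diaconis rule, uniform edges.

    `n` is the number of samples per trial; defaults to len(x).  Degenerate
    inputs (zero range or zero IQR) collapse to a single bin.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        raise ValueError("empty sample")
    n = len(x) if n is None else n
    lo, hi = float(np.min(x)), float(np.max(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if hi == lo or iqr == 0:
        logger.info("degenerate sample for binning (range %.3g, iqr %.3g): k=1", hi - lo, iqr)
        return BinningSpec(k=1, edges=np.array([lo, hi if hi > lo else lo + 1.0]))
    k = max(1, int(round((hi - lo) / (coefficient * iqr * n ** (-1.0 / 3.0)))))
    return BinningSpec(k=k, edges=np.linspace(lo, hi, k + 1))


def session_bins(
    x: np.ndarray,
    trial_index: np.ndarray | None = None,
    coefficient: float = 2.5,
) -> BinningSpec:
    """Session-wide binning: k computed per trial, median k, uniform edges
    over the whole-session range."""
    x = np.asarray(x, dtype=float)
    finite = np.isfinite(x)
    if trial_index is None:
        return fd_bins(x[finite], coefficient=coefficient)
    trial_index = np.asarray(trial_index)
    ks = []
    for tid in np.unique(trial_index[trial_index >= 0]):
        xi = x[(trial_index == tid) & finite]
        if len(xi) >= 10:
            ks.append(fd_bins(xi, coefficient=coefficient).k)
    if not ks:
        return fd_bins(x[finite], coefficient=coefficient)
    k = max(1, int(round(np.median(ks))))
    lo, hi = float(np.min(x[finite])), float(np.max(x[finite]))
    if hi == lo:
        return BinningSpec(k=1, edges=np.array([lo, lo + 1.0]))
    return BinningSpec(k=k, edges=np.linspace(lo, hi, k + 1))


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    binning_x: BinningSpec,
    binning_y: BinningSpec,
) -> float:
    """Plug-in Shannon mutual information in bits over the joint histogram."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    xi, yi = binning_x.digitize(x[ok]), binning_y.digitize(y[ok])
    joint = np.zeros((binning_x.k, binning_y.k))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (px * py)
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return float(terms.sum())


def time_shifted_mi(
    dff: np.ndarray,
    variable: np.ndarray,
    trial_index: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """MI as a function of calcium delay, +/-1000 ms in 100-ms steps.

    A positive delay d pairs dff(t) with variable(t - d), i.e. the calcium
    signal lags the behavior.  Returns the full profile plus the value at
    the 200-ms analysis delay.
    """
    config = config or PipelineConfig()
    dff = np.asarray(dff, dtype=float)
    variable = np.asarray(variable, dtype=float)
    bx = session_bins(dff, trial_index, config.mi_fd_coefficient)
    by = session_bins(variable, trial_index, config.mi_fd_coefficient)
    max_shift = int(round(config.mi_max_shift_ms / 1000.0 * IMAGING_RATE_HZ))
    step = max(1, int(round(config.mi_shift_step_ms / 1000.0 * IMAGING_RATE_HZ)))
    delays, mis = [], []
    for d in range(-max_shift, max_shift + 1, step):
        if d > 0:
            xs, ys = dff[d:], variable[:-d]
        elif d < 0:
            xs, ys = dff[:d], variable[-d:]
        else:
            xs, ys = dff, variable
        delays.append(d / IMAGING_RATE_HZ * 1000.0)
        mis.append(mutual_information(xs, ys, bx, by))
    delays = np.array(delays)
    mis = np.array(mis)
    d_analysis = config.mi_analysis_delay_ms
    at = int(np.argmin(np.abs(delays - d_analysis)))
    return {
        "delays_ms": delays,
        "mi_bits": mis,
        "mi_at_analysis_delay": float(mis[at]),
        "peak_delay_ms": float(delays[int(np.argmax(mis))]),
    }


def mi_condition_compare(
    dff: np.ndarray,
    variable: np.ndarray,
    touch_flag: np.ndarray,
    trial_index: np.ndarray | None = None,
    config: PipelineConfig | None = None,
) -> dict:
    """I during touch minus I during no-touch, at the 200-ms calcium delay.

    Shared session-wide bin edges keep the two condition estimates
    comparable; either condition below 10% of frames makes the result
    missing.
    """
    config = config or PipelineConfig()
    dff = np.asarray(dff, dtype=float)
    variable = np.asarray(variable, dtype=float)
    touch = np.asarray(touch_flag).astype(bool)
    d = int(round(config.mi_analysis_delay_ms / 1000.0 * IMAGING_RATE_HZ))
    if d > 0:
        xs, ys, cond = dff[d:], variable[:-d], touch[d:]
        ti = None if trial_index is None else np.asarray(trial_index)[d:]
    else:
        xs, ys, cond = dff, variable, touch
        ti = trial_index
    frac = cond.mean()
    if min(frac, 1 - frac) < config.mi_min_condition_fraction:
        logger.info("condition fractions %.2f/%.2f below 10%%: MI comparison missing",
                    frac, 1 - frac)
        return {"mi_touch": np.nan, "mi_no_touch": np.nan, "delta_i": np.nan}
    bx = session_bins(xs, ti, config.mi_fd_coefficient)
    by = session_bins(ys, ti, config.mi_fd_coefficient)
    mi_t = mutual_information(xs[cond], ys[cond], bx, by)
    mi_n = mutual_information(xs[~cond], ys[~cond], bx, by)
    return {"mi_touch": mi_t, "mi_no_touch": mi_n, "delta_i": mi_t - mi_n}
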