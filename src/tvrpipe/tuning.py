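"""Run-speed tuning: equal-occupancy binning, ANOVA gate, constrained fits.

Speeds above the 1 cm/s stationary threshold are divided into bins covering
equal amounts of recording time (empirical quantiles); a neuron passes the
speed-modulation gate when a one-way ANOVA of per-frame dF/F across bins
gives p < 1e-3.  Tuning curves are piecewise Gaussians

    y(s) = y_max * exp(-(s - s_max)^2 / sigma_s),

with sigma_s = sigma_minus below the preferred speed s_max and sigma_plus
above it (sigma_s carries units (cm/s)^2 as printed).  Three constrained
fits are compared: monotonically increasing (s_max above the session's
maximum speed), monotonically decreasing (s_max <= 1 cm/s), and band-pass
(s_max free).  Fits use 80% of the frames (stratified by bin, seeded) and
are scored by the fraction of explained variance on the held-out 20%; a
neuron is classified only when the best fit explains at least 30% of the
test variance, and band-pass additionally requires 1 < s_max < max speed
and a better test EV than both monotone fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import f_oneway

from .config import PipelineConfig

TUNING_CLASSES = ("increasing", "decreasing", "band_pass", "unclassified")


@dataclass
class SpeedBinning:
    edges: np.ndarray               # k+1 quantile edges over eligible speeds
    stationary_threshold: float     # cm/s; below -> stationary bin, excluded

    @property
    def k(self) -> int:
        return len(self.edges) - 1

    def assign(self, speeds: np.ndarray) -> np.ndarray:
        """Bin index per frame; -1 marks the stationary bin."""
        speeds = np.asarray(speeds, dtype=float)
        idx = np.clip(np.digitize(speeds, self.edges[1:-1]), 0, self.k - 1)
        idx[speeds <= self.stationary_threshold] = -1
        return idx

    def centers(self, speeds: np.ndarray) -> np.ndarray:
        """Mean eligible speed per bin (empirical bin centers)."""
        idx = self.assign(speeds)
        return np.array([np.mean(speeds[idx == b]) for b in range(self.k)])


@dataclass
class TuningFit:
    y_max: float = np.nan
    s_max: float = np.nan
    sigma_minus: float = np.nan
    sigma_plus: float = np.nan
    tuning_class: str = "unclassified"
    explained_variance: float = np.nan
    ev_by_regime: dict = field(default_factory=dict)
    anova_p: float = np.nan
    modulated: bool = False


def equal_occupancy_bins(
    speeds: np.ndarray,
    k: int = 10,
    stationary_threshold: float = 1.0,
    min_frames_per_bin: int = 10,
) -> SpeedBinning:
    """Quantile bin edges so each non-stationary bin covers equal time."""
    speeds = np.asarray(speeds, dtype=float)
    eligible = speeds[speeds > stationary_threshold]
    if len(eligible) < k * min_frames_per_bin:
        raise ValueError(
            f"only {len(eligible)} frames above {stationary_threshold} cm/s; "
            f"need at least {k * min_frames_per_bin} for {k} bins"
        )
    edges = np.quantile(eligible, np.linspace(0, 1, k + 1))
    if np.any(np.diff(edges) <= 0):
        raise ValueError("degenerate speed distribution: quantile edges collapse")
    return SpeedBinning(edges=edges, stationary_threshold=stationary_threshold)


def speed_anova(
    dff: np.ndarray,
    speeds: np.ndarray,
    binning: SpeedBinning,
    alpha: float = 1e-3,
) -> tuple[float, bool]:
    """One-way ANOVA of per-frame dF/F across speed bins (stationary excluded)."""
    dff = np.asarray(dff, dtype=float)
    idx = binning.assign(speeds)
    groups = []
    for b in range(binning.k):
        g = dff[(idx == b) & np.isfinite(dff)]
        if len(g) >= 2:
            groups.append(g)
    if len(groups) < 2:
        return np.nan, False
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return np.nan, False
    _, p = f_oneway(*groups)
    if not np.isfinite(p):
        return np.nan, False
    return float(p), bool(p < alpha)


# --------------------------------------------------------------------------
# constrained Gaussian fits
# --------------------------------------------------------------------------

def _tuning_curve(s, y_max, s_max, sig_minus, sig_plus):
    sig = np.where(np.asarray(s) < s_max, sig_minus, sig_plus)
    return y_max * np.exp(-((np.asarray(s) - s_max) ** 2) / sig)


def _fit_regime(centers, means, s_bounds, rng, n_starts=5):
    """Multi-start bounded least squares for one s_max regime."""
    scale = max(np.max(np.abs(means)), 1e-9)
    span = max(centers.max() - centers.min(), 1e-3)
    lo = [-2 * scale, s_bounds[0], 1e-3, 1e-3]
    hi = [2 * scale, s_bounds[1], (10 * span) ** 2, (10 * span) ** 2]
    best = None
    for _ in range(n_starts):
        p0 = [
            float(np.clip(means[np.argmax(np.abs(means))], lo[0], hi[0])),
            rng.uniform(s_bounds[0], s_bounds[1]),
            rng.uniform(0.5, 4) * span,
            rng.uniform(0.5, 4) * span,
        ]
        p0[2:] = np.clip(p0[2:], lo[2], hi[2])
        try:
            res = least_squares(
                lambda p: _tuning_curve(centers, *p) - means,
                p0, bounds=(lo, hi), xtol=1e-8, ftol=1e-8,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def _test_ev(params, centers, test_means):
    pred = _tuning_curve(centers, *params)
    ss_tot = np.sum((test_means - np.mean(test_means)) ** 2)
    if ss_tot == 0:
        return np.nan
    return float(1.0 - np.sum((test_means - pred) ** 2) / ss_tot)


def fit_speed_tuning(
    speeds: np.ndarray,
    dff: np.ndarray,
    binning: SpeedBinning | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> TuningFit:
    """Full tuning analysis of one neuron: gate, three fits, class.

    Frames are split 80/20 stratified by speed bin; per-bin mean dF/F from
    the training frames is fitted, per-bin means from the held-out frames
    score the explained variance.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    speeds = np.asarray(speeds, dtype=float)
    dff = np.asarray(dff, dtype=float)
    if binning is None:
        binning = equal_occupancy_bins(
            speeds, config.n_speed_bins, config.stationary_speed_cms
        )
    if binning.k < 5:
        raise ValueError("need at least 5 non-stationary bins for tuning fits")
    out = TuningFit()
    out.anova_p, out.modulated = speed_anova(dff, speeds, binning, config.anova_alpha)

    idx = binning.assign(speeds)
    train_mask = np.zeros(len(speeds), dtype=bool)
    for b in range(binning.k):
        rows = np.nonzero((idx == b) & np.isfinite(dff))[0]
        rng.shuffle(rows)
        n_train = int(round(config.tuning_train_fraction * len(rows)))
        train_mask[rows[:n_train]] = True
    test_mask = (idx >= 0) & np.isfinite(dff) & ~train_mask

    def bin_means(mask):
        return np.array(
            [np.mean(dff[mask & (idx == b)]) if (mask & (idx == b)).any() else np.nan
             for b in range(binning.k)]
        )

    train_means = bin_means(train_mask)
    test_means = bin_means(test_mask)
    if np.isnan(train_means).any() or np.isnan(test_means).any():
        return out
    centers = np.array(
        [np.mean(speeds[train_mask & (idx == b)]) for b in range(binning.k)]
    )
    max_speed = float(np.nanmax(speeds))
    regimes = {
        "increasing": (max_speed, 5 * max_speed),
        "decreasing": (0.0, binning.stationary_threshold),
        "band_pass": (0.1, 1.5 * max_speed),
    }
    fits, evs = {}, {}
    for name, s_bounds in regimes.items():
        res = _fit_regime(centers, train_means, s_bounds, rng, config.tuning_n_starts)
        if res is None:
            evs[name] = 0.0  # non-convergence scores zero
            continue
        fits[name] = res.x
        evs[name] = _test_ev(res.x, centers, test_means)
    out.ev_by_regime = {k: (v if np.isfinite(v) else 0.0) for k, v in evs.items()}

    band_valid = (
        "band_pass" in fits
        and binning.stationary_threshold < fits["band_pass"][1] < max_speed
        and out.ev_by_regime["band_pass"] > out.ev_by_regime.get("increasing", 0.0)
        and out.ev_by_regime["band_pass"] > out.ev_by_regime.get("decreasing", 0.0)
    )
    if band_valid:
        chosen = "band_pass"
    else:
        mono = {n: out.ev_by_regime.get(n, 0.0) for n in ("increasing", "decreasing")}
        chosen = max(mono, key=mono.get)
    if chosen in fits:
        out.y_max, out.s_max, out.sigma_minus, out.sigma_plus = fits[chosen]
        out.explained_variance = out.ev_by_regime[chosen]
        out.tuning_class = chosen if out.explained_variance >= config.tuning_ev_floor else "unclassified"
    return out
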