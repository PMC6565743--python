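"""Bootstrap functional classification of neurons from open-loop sessions.

Each neuron's smoothed (500-ms first-order Savitzky-Golay) dF/F is averaged
in the four stimulus-behavior conditions — no-running/no-touch, running
without touch, touch without running, and concurrent running and touch —
over 100 trial-level bootstrap replicates (trials resampled with
replacement, frames pooled by condition).  A neuron is initially assigned
to the condition with the largest bootstrap-mean dF/F (rest / run / touch /
integrative); if the margin to the second-largest condition is smaller than
the bootstrap standard deviation of the top condition, the neuron is
demoted to the second-largest group, so a cell counts as integrative only
when the combination genuinely exceeds its best single component.

Population statistics resample sessions (11 of the available sessions, 10
draws) and compare per-category percentages between cortical layers with a
two-sample t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.stats import ttest_ind

from .config import IMAGING_RATE_HZ, PipelineConfig

logger = logging.getLogger(__name__)

CONDITION_ORDER = ("norun_notouch", "run_notouch", "norun_touch", "run_touch")
CONDITION_TO_CATEGORY = {
    "norun_notouch": "rest",
    "run_notouch": "run",
    "norun_touch": "touch",
    "run_touch": "integrative",
}
CATEGORIES = tuple(CONDITION_TO_CATEGORY.values())


class ConditionNotRealized(ValueError):
    """A stimulus-behavior condition has no frames; session excluded."""


@dataclass
class ConditionMeans:
    means: dict[str, float]
    sds: dict[str, float]          # bootstrap SD of each condition mean
    n_bootstrap: int


@dataclass
class CategoryResult:
    category: str
    margin: float                  # first minus second largest mean
    demoted: bool
    condition_means: ConditionMeans | None = None


def condition_labels(running: np.ndarray, touch: np.ndarray) -> np.ndarray:
    """Per-frame condition name from the running bit and the touch flag."""
    running = np.asarray(running, dtype=bool)
    touch = np.asarray(touch, dtype=bool)
    idx = 2 * running.astype(int) + touch.astype(int)
    lut = np.array(
        ["norun_notouch", "norun_touch", "run_notouch", "run_touch"], dtype=object
    )
    return lut[idx]


def bootstrap_condition_means(
    dff: np.ndarray,
    running: np.ndarray,
    touch: np.ndarray,
    trial_index: np.ndarray,
    n_bootstrap: int = 100,
    seed: int = 0,
    smooth_window_s: float = 0.5,
) -> ConditionMeans:
    """Trial-bootstrap condition means and their SDs for one neuron.

    Frames outside any trial (trial_index < 0) are ignored.  Raises
    ConditionNotRealized when any of the four conditions has no frames in
    the session at all.
    """
    dff = np.asarray(dff, dtype=float)
    win = int(round(smooth_window_s * IMAGING_RATE_HZ))
    win += (win + 1) % 2
    smoothed = savgol_filter(dff, win, 1, mode="interp") if win >= 3 and len(dff) >= win else dff
    labels = condition_labels(running, touch)
    trial_index = np.asarray(trial_index)
    in_trial = trial_index >= 0
    for cond in CONDITION_ORDER:
        if not np.any(in_trial & (labels == cond) & np.isfinite(smoothed)):
            raise ConditionNotRealized(f"condition {cond} has no frames")
    trial_ids = np.unique(trial_index[in_trial])
    n_trials = len(trial_ids)
    tpos = {tid: j for j, tid in enumerate(trial_ids)}
    # per-trial, per-condition frame sums and counts; a bootstrap replicate's
    # condition mean is then a weighted combination of these
    sums = np.zeros((n_trials, 4))
    counts = np.zeros((n_trials, 4))
    finite = np.isfinite(smoothed)
    cond_idx = {c: k for k, c in enumerate(CONDITION_ORDER)}
    for tid in trial_ids:
        tmask = (trial_index == tid) & finite
        for c, k in cond_idx.items():
            sel = tmask & (labels == c)
            sums[tpos[tid], k] = smoothed[sel].sum()
            counts[tpos[tid], k] = sel.sum()
    rng = np.random.default_rng(seed)
    reps = np.full((n_bootstrap, 4), np.nan)
    for r in range(n_bootstrap):
        draw = rng.choice(n_trials, size=n_trials, replace=True)
        w = np.bincount(draw, minlength=n_trials).astype(float)
        s = w @ sums
        n = w @ counts
        with np.errstate(invalid="ignore", divide="ignore"):
            reps[r] = np.where(n > 0, s / n, np.nan)
    means = {c: float(np.nanmean(reps[:, k])) for c, k in cond_idx.items()}
    sds = {c: float(np.nanstd(reps[:, k], ddof=0)) for c, k in cond_idx.items()}
    return ConditionMeans(means=means, sds=sds, n_bootstrap=n_bootstrap)


_SPECIFICITY = {  # number of stimulus/behavior components in the condition
    "norun_notouch": 0,
    "run_notouch": 1,
    "norun_touch": 1,
    "run_touch": 2,
}


def classify(cm: ConditionMeans) -> CategoryResult:
    """Argmax over condition means with the one-SD demotion rule.

    The demotion is conservative by intent: a cell keeps a compound label
    (integrative) only when its compound response exceeds the best single
    component by more than the bootstrap SD of the top condition.  Demotion
    therefore only ever moves toward the *less specific* of the top two
    conditions; when the runner-up is the more specific one (e.g. a run
    cell whose run+touch mean statistically ties its run-alone mean) the
    argmax stands, since promoting on a tie would contradict the rule's
    purpose.  Exact ties break toward the less specific condition.
    """
    order = sorted(
        range(4),
        key=lambda i: (-cm.means[CONDITION_ORDER[i]], i),
    )
    first, second = CONDITION_ORDER[order[0]], CONDITION_ORDER[order[1]]
    margin = cm.means[first] - cm.means[second]
    demoted = margin < cm.sds[first] and _SPECIFICITY[second] < _SPECIFICITY[first]
    winner = second if demoted else first
    return CategoryResult(
        category=CONDITION_TO_CATEGORY[winner],
        margin=float(margin),
        demoted=bool(demoted),
        condition_means=cm,
    )


def category_distribution_stats(
    table: pd.DataFrame,
    n_draws: int = 10,
    draw_size: int = 11,
    seed: int = 0,
    max_redraws: int = 100,
) -> dict:
    """Session-resampled category percentages per layer, with per-category
    two-sample t-tests between layers.

    `table` needs columns session, layer, category (one row per neuron).
    Each draw selects `draw_size` sessions without replacement; draws in
    which a layer ends up with zero neurons are redrawn (logged).
    """
    required = {"session", "layer", "category"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    sessions = np.array(sorted(table["session"].unique()))
    if len(sessions) < draw_size:
        raise ValueError(f"need at least {draw_size} sessions, have {len(sessions)}")
    layers = sorted(table["layer"].unique())
    rng = np.random.default_rng(seed)
    pct = {layer: {c: [] for c in CATEGORIES} for layer in layers}
    for _ in range(n_draws):
        for attempt in range(max_redraws):
            chosen = rng.choice(sessions, size=draw_size, replace=False)
            sub = table[table["session"].isin(chosen)]
            if all((sub["layer"] == layer).sum() > 0 for layer in layers):
                break
            logger.info("draw redrawn: a layer had zero neurons (attempt %d)", attempt + 1)
        else:
            raise RuntimeError("could not draw sessions covering every layer")
        for layer in layers:
            grp = sub[sub["layer"] == layer]
            for c in CATEGORIES:
                pct[layer][c].append(100.0 * np.mean(grp["category"] == c))
    out = {
        "per_layer": {
            layer: {
                c: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
                for c, v in pct[layer].items()
            }
            for layer in layers
        }
    }
    if len(layers) == 2:
        a, b = layers
        out["t_tests"] = {}
        for c in CATEGORIES:
            t, p = ttest_ind(pct[a][c], pct[b][c])
            out["t_tests"][c] = {"t": float(t), "p": float(p)}
    return out
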