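"""Time-shifted ensemble-tree encoding of calcium signals.

A random forest (32 trees, minimum leaf size 10) predicts each neuron's
dF/F during whisker-contact periods from run speed, texture-rotation speed
and the whisking envelope, each entered at seven time shifts (+/-300 ms at
the 10-Hz imaging rate, p = 3), for a design of N x (2p + 1) = 21 columns.
The model is trained on 80% of the frames and scored on the remaining 20%,
drawn as non-overlapping 2-s contiguous chunks; the procedure repeats five
times and the fraction of explained variance

    Q_i = 1 - sum_t (y - y_hat)^2 / sum_t (y - mu_train)^2

is clipped at zero and averaged into Q-bar.  Predictor importance is the
drop in Q-bar when that predictor's columns (all shifts together) are
permuted in time on the test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .config import IMAGING_RATE_HZ, PipelineConfig

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = ("run_speed", "texture_speed", "whisk_envelope")


@dataclass
class EncodingResult:
    q_bar: float
    q_i: list[float]
    predictor_names: list[str]
    n_frames: int
    shuffle_importance: dict[str, float] = field(default_factory=dict)
    _repeats: list = field(default_factory=list, repr=False)  # (model, X_te, y_te, mu_tr, denom)


def build_design(
    predictors: dict[str, np.ndarray], p: int = 3
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Design matrix of every predictor at shifts -p..p frames.

    Shifted copies are edge-padded; returns (X, column names, map from
    predictor name to its column indices).
    """
    names = list(predictors)
    n = len(next(iter(predictors.values())))
    cols, col_names, col_map = [], [], {}
    for name in names:
        x = np.asarray(predictors[name], dtype=float)
        if len(x) != n:
            raise ValueError("predictors differ in length")
        col_map[name] = []
        for s in range(-p, p + 1):
            shifted = np.empty(n)
            if s > 0:
                shifted[s:] = x[:-s]
                shifted[:s] = x[0]
            elif s < 0:
                shifted[:s] = x[-s:]
                shifted[s:] = x[-1]
            else:
                shifted[:] = x
            col_map[name].append(len(cols))
            cols.append(shifted)
            col_names.append(f"{name}@{s:+d}")
    return np.column_stack(cols), col_names, col_map


def _chunked_test_indices(n_rows, chunk_len, test_fraction, rng):
    """Non-overlapping contiguous chunks drawn until test_fraction covered."""
    target = int(round(test_fraction * n_rows))
    starts = rng.permutation(max(1, n_rows - chunk_len + 1))
    taken = np.zeros(n_rows, dtype=bool)
    covered = 0
    for s in starts:
        seg = slice(s, min(s + chunk_len, n_rows))
        if taken[seg].any():
            continue
        taken[seg] = True
        covered += seg.stop - seg.start
        if covered >= target:
            break
    return np.nonzero(taken)[0]


def fit_encoding_model(
    dff: np.ndarray,
    predictors: dict[str, np.ndarray],
    mask: np.ndarray | None = None,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> EncodingResult:
    """Fit the time-shifted random-forest encoding model for one neuron.

    `mask` restricts rows (touch frames for the published analysis); the
    time-shifted predictor columns are built on the full timeline first, so
    shifted values may reach outside the mask.
    """
    config = config or PipelineConfig()
    dff = np.asarray(dff, dtype=float)
    X_full, _, col_map = build_design(predictors, config.encoding_max_shift_frames)
    rows = np.isfinite(dff) & np.all(np.isfinite(X_full), axis=1)
    if mask is not None:
        rows &= np.asarray(mask).astype(bool)
    X, y = X_full[rows], dff[rows]
    if len(y) < 100:
        raise ValueError(f"only {len(y)} usable frames; need at least 100")
    if np.ptp(y) == 0:
        logger.warning("constant target: explained variance undefined, Q=0")
        return EncodingResult(0.0, [0.0] * config.encoding_n_repeats, list(predictors), len(y))

    chunk_len = int(round(config.encoding_chunk_s * IMAGING_RATE_HZ))
    rng = np.random.default_rng(seed)
    q_i, repeats = [], []
    for rep in range(config.encoding_n_repeats):
        test_idx = _chunked_test_indices(len(y), chunk_len, config.encoding_test_fraction, rng)
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[test_idx] = False
        X_tr, y_tr = X[train_mask], y[train_mask]
        X_te, y_te = X[test_idx], y[test_idx]
        model = RandomForestRegressor(
            n_estimators=config.rf_n_trees,
            min_samples_leaf=config.rf_min_leaf,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        model.fit(X_tr, y_tr)
        mu = float(np.mean(y_tr))
        denom = float(np.sum((y_te - mu) ** 2))
        if denom == 0:
            q = 0.0
        else:
            q = 1.0 - float(np.sum((y_te - model.predict(X_te)) ** 2)) / denom
        q_i.append(max(0.0, q))
        repeats.append((model, X_te, y_te, mu, denom))
    result = EncodingResult(
        q_bar=float(np.mean(q_i)),
        q_i=q_i,
        predictor_names=list(predictors),
        n_frames=len(y),
        _repeats=repeats,
    )
    result._col_map = col_map
    return result


def shuffle_importance(
    result: EncodingResult, predictor: str, seed: int = 0
) -> float:
    """Drop in Q-bar when one predictor's test-set columns are permuted.

    All seven shifted copies of the predictor are permuted together with a
    single global permutation of test rows per repeat, so the predictor's
    temporal relation to the target is destroyed while its marginal
    distribution is preserved.
    """
    col_map = getattr(result, "_col_map", None)
    if col_map is None or predictor not in col_map:
        raise ValueError(f"no fitted context for predictor {predictor!r}")
    rng = np.random.default_rng(seed)
    q_shuf = []
    for model, X_te, y_te, mu, denom in result._repeats:
        Xs = X_te.copy()
        perm = rng.permutation(len(Xs))
        Xs[:, col_map[predictor]] = Xs[perm][:, col_map[predictor]]
        if denom == 0:
            q_shuf.append(0.0)
            continue
        q = 1.0 - float(np.sum((y_te - model.predict(Xs)) ** 2)) / denom
        q_shuf.append(max(0.0, q))
    return result.q_bar - float(np.mean(q_shuf))


def all_shuffle_importances(result: EncodingResult, seed: int = 0) -> dict[str, float]:
    out = {}
    for i, name in enumerate(result.predictor_names):
        out[name] = shuffle_importance(result, name, seed=seed + i)
    result.shuffle_importance = out
    return out
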