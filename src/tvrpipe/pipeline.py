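"""End-to-end pipeline runner.

Executes preprocess -> segment -> respond -> tuning -> classify -> mi ->
encode over one or more session directories, writing per-stage CSVs into
each session's output folder and a machine-readable report.json at the
cohort level.  Every stochastic step draws its seed deterministically from
(global seed, stage name, session id), so a report is byte-identical across
reruns with the same config.  A failing stage isolates its session: the
error is recorded and the run continues.
"""

from __future__ import annotations

import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, encoding, info, preprocess, response, segmentation, tuning
from .bundle import SessionBundle, read_session
from .config import PipelineConfig, stage_seed

logger = logging.getLogger(__name__)


def _neuron_backgrounds(bundle: SessionBundle) -> list[float]:
    """Per-neuron background: generator ground truth when present, else the
    1st percentile of the neuron's own raw trace."""
    gt = bundle.ground_truth or {}
    neurons = gt.get("neurons")
    if neurons is not None:
        return [n["spec"]["background"] for n in neurons]
    return [float(np.percentile(row, 1)) for row in bundle.fluo]


def preprocess_stage(bundle: SessionBundle) -> tuple[np.ndarray, pd.DataFrame]:
    """dF/F matrix and per-neuron trace statistics."""
    if bundle.fluo is None:
        raise ValueError("session has no fluorescence")
    backgrounds = _neuron_backgrounds(bundle)
    dff = np.empty_like(bundle.fluo, dtype=float)
    rows = []
    for i, (trace, bg) in enumerate(zip(bundle.fluo, backgrounds)):
        d, stats = preprocess.trace_stats(trace, bg)
        dff[i] = d
        rows.append({"neuron": i, "f0": stats.f0, "sigma": stats.sigma, "snr": stats.snr})
    return dff, pd.DataFrame(rows)


def events_stage(
    bundle: SessionBundle,
    states: segmentation.StateTimeline,
    config: PipelineConfig,
) -> dict[str, segmentation.EventSet]:
    whisk = segmentation.detect_onsets(
        states.whisking, "whisk_onset", config.min_off_s, config.min_on_s,
        truncate_at=states.running,
    )
    run = segmentation.detect_onsets(
        states.running, "run_onset", config.min_off_s, config.min_on_s
    )
    touch, controls = segmentation.touch_onsets(bundle.stage_moving_flag, bundle.contact_flag)
    touch_run, touch_rest = segmentation.split_touch_events(touch, states.speed, config)
    pert_run, pert_rest = segmentation.select_perturbations(
        bundle.perturbation_flag, states.speed, config
    )
    return {
        "whisk_onset": whisk,
        "run_onset": run,
        "touch_onset": touch,
        "sound_control": controls,
        "touch_during_running": touch_run,
        "touch_during_resting": touch_rest,
        "perturbation_running": pert_run,
        "perturbation_resting": pert_rest,
    }


def events_to_frame(events: dict[str, segmentation.EventSet]) -> pd.DataFrame:
    rows = []
    for kind, ev in events.items():
        for k in range(len(ev)):
            rows.append(
                {
                    "kind": kind,
                    "onset_s": ev.times[k],
                    "end_s": ev.ends[k],
                    "context_speed": np.nan if ev.context_speed is None else ev.context_speed[k],
                }
            )
    return pd.DataFrame(rows, columns=["kind", "onset_s", "end_s", "context_speed"])


def respond_stage(
    dff: np.ndarray,
    stats: pd.DataFrame,
    states: segmentation.StateTimeline,
    events: dict[str, segmentation.EventSet],
    config: PipelineConfig,
) -> pd.DataFrame:
    rows = []
    for i in range(dff.shape[0]):
        r = response.neuron_response(
            dff[i],
            float(stats.loc[stats["neuron"] == i, "sigma"].iloc[0]),
            states,
            whisk_events=events["whisk_onset"],
            run_events=events["run_onset"],
            touch_events=events["touch_onset"],
            perturb_events=events["perturbation_running"],
            config=config,
        )
        rows.append({"neuron": i, **r.__dict__})
    return pd.DataFrame(rows)


def tuning_stage(
    dff: np.ndarray,
    states: segmentation.StateTimeline,
    config: PipelineConfig,
    seed: int,
) -> pd.DataFrame:
    rows = []
    try:
        binning = tuning.equal_occupancy_bins(
            states.speed, config.n_speed_bins, config.stationary_speed_cms
        )
    except ValueError as err:
        logger.info("speed tuning skipped: %s", err)
        return pd.DataFrame()
    for i in range(dff.shape[0]):
        fit = tuning.fit_speed_tuning(states.speed, dff[i], binning, config, seed=seed + i)
        rows.append(
            {
                "neuron": i,
                "anova_p": fit.anova_p,
                "modulated": fit.modulated,
                "tuning_class": fit.tuning_class,
                "y_max": fit.y_max,
                "s_max": fit.s_max,
                "sigma_minus": fit.sigma_minus,
                "sigma_plus": fit.sigma_plus,
                "explained_variance": fit.explained_variance,
            }
        )
    return pd.DataFrame(rows)


def classify_stage(
    dff: np.ndarray,
    bundle: SessionBundle,
    states: segmentation.StateTimeline,
    config: PipelineConfig,
    seed: int,
) -> pd.DataFrame:
    if bundle.meta.get("condition") != "open_loop":
        logger.info("classification requires an open-loop session; skipped")
        return pd.DataFrame()
    trial_index = bundle.trial_index_of_frames()
    rows = []
    for i in range(dff.shape[0]):
        try:
            cm = classification.bootstrap_condition_means(
                dff[i], states.running, states.touch, trial_index,
                n_bootstrap=config.n_bootstrap, seed=seed + i,
                smooth_window_s=config.event_smooth_window_s,
            )
        except classification.ConditionNotRealized as err:
            logger.info("session excluded from classification: %s", err)
            return pd.DataFrame()
        res = classification.classify(cm)
        rows.append(
            {
                "neuron": i,
                "category": res.category,
                "margin": res.margin,
                "demoted": res.demoted,
                **{f"mean_{c}": cm.means[c] for c in classification.CONDITION_ORDER},
                **{f"sd_{c}": cm.sds[c] for c in classification.CONDITION_ORDER},
            }
        )
    return pd.DataFrame(rows)


def mi_stage(
    dff: np.ndarray,
    bundle: SessionBundle,
    states: segmentation.StateTimeline,
    config: PipelineConfig,
) -> pd.DataFrame:
    run_frac = float(np.mean(states.running))
    if min(run_frac, 1 - run_frac) < config.mi_min_condition_fraction:
        logger.info("MI skipped: running fraction %.2f outside [0.1, 0.9]", run_frac)
        return pd.DataFrame()
    trial_index = bundle.trial_index_of_frames()
    rows = []
    for i in range(dff.shape[0]):
        for var_name, var in (
            ("run_speed", states.speed),
            ("texture_speed", bundle.texture_speed),
        ):
            scan = info.time_shifted_mi(dff[i], var, trial_index, config)
            row = {
                "neuron": i,
                "variable": var_name,
                "mi_bits": scan["mi_at_analysis_delay"],
                "peak_delay_ms": scan["peak_delay_ms"],
            }
            if var_name == "run_speed":
                cmp = info.mi_condition_compare(
                    dff[i], var, bundle.contact_flag, trial_index, config
                )
                row.update(
                    mi_touch=cmp["mi_touch"],
                    mi_no_touch=cmp["mi_no_touch"],
                    delta_i=cmp["delta_i"],
                )
            rows.append(row)
    return pd.DataFrame(rows)


def encode_stage(
    dff: np.ndarray,
    bundle: SessionBundle,
    states: segmentation.StateTimeline,
    config: PipelineConfig,
    seed: int,
) -> pd.DataFrame:
    touch_mask = np.asarray(bundle.contact_flag).astype(bool)
    if touch_mask.sum() < 100:
        logger.info("encoding skipped: only %d touch frames", int(touch_mask.sum()))
        return pd.DataFrame()
    predictors = {
        "run_speed": states.speed,
        "texture_speed": np.asarray(bundle.texture_speed, dtype=float),
        "whisk_envelope": states.whisk_envelope,
    }
    rows = []
    for i in range(dff.shape[0]):
        res = encoding.fit_encoding_model(dff[i], predictors, touch_mask, config, seed=seed + i)
        imp = encoding.all_shuffle_importances(res, seed=seed + 1000 + i)
        rows.append(
            {
                "neuron": i,
                "q_bar": res.q_bar,
                **{f"q_{j}": q for j, q in enumerate(res.q_i)},
                **{f"dq_{name}": imp[name] for name in res.predictor_names},
            }
        )
    return pd.DataFrame(rows)


def run_session(
    bundle: SessionBundle,
    session_id: str,
    config: PipelineConfig,
    out_dir: Path | None = None,
) -> dict:
    """All stages for one session; returns tables plus a summary dict."""
    tables: dict[str, pd.DataFrame] = {}
    dff, stats = preprocess_stage(bundle)
    tables["trace_stats"] = stats
    states = segmentation.segment_session(bundle, config)
    tables["states_10hz"] = states.to_frame()
    events = events_stage(bundle, states, config)
    tables["events"] = events_to_frame(events)
    tables["neuron_responses"] = respond_stage(dff, stats, states, events, config)
    tables["speed_tuning"] = tuning_stage(
        dff, states, config, stage_seed(config.seed, "tuning", session_id)
    )
    tables["categories"] = classify_stage(
        dff, bundle, states, config, stage_seed(config.seed, "classify", session_id)
    )
    tables["mi_results"] = mi_stage(dff, bundle, states, config)
    tables["encoding_results"] = encode_stage(
        dff, bundle, states, config, stage_seed(config.seed, "encode", session_id)
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.8g")
    summary = {
        "session": session_id,
        "condition": bundle.meta.get("condition"),
        "layer": bundle.meta.get("layer"),
        "n_neurons": bundle.n_neurons,
        "n_frames": bundle.n_frames,
        "occupancy": segmentation.StateTimeline.occupancy(states),
        "n_events": {k: len(v) for k, v in events.items()},
        "stages_run": [k for k, v in tables.items() if len(v)],
    }
    return {"tables": tables, "summary": summary}


def run_pipeline(
    config: PipelineConfig,
    sessions: dict[str, SessionBundle] | list[str | Path],
    out_dir: str | Path,
) -> dict:
    """Run every stage over a cohort of sessions and write report.json.

    `sessions` is either {session_id: bundle} or a list of session
    directories.  A stage failure inside one session is caught, reported,
    and the remaining sessions still run.
    """
    if not sessions:
        raise ValueError("need at least one session")
    if not isinstance(sessions, dict):
        sessions = {Path(p).name: read_session(p) for p in sessions}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = {"config": config.to_dict(), "sessions": {}, "errors": {}}
    all_categories = []
    for sid, bundle in sessions.items():
        try:
            res = run_session(bundle, sid, config, out_dir / sid)
            report["sessions"][sid] = res["summary"]
            cats = res["tables"]["categories"]
            if len(cats):
                cats = cats.assign(session=sid, layer=bundle.meta.get("layer", ""))
                all_categories.append(cats)
        except Exception as err:  # noqa: BLE001 - session isolation by design
            logger.error("session %s failed: %s", sid, err)
            report["errors"][sid] = {
                "error": str(err),
                "traceback": traceback.format_exc(),
            }
    if all_categories:
        cat_table = pd.concat(all_categories, ignore_index=True)
        cat_table.to_csv(out_dir / "categories.csv", index=False)
        if cat_table["session"].nunique() >= config.session_draw_size:
            stats = classification.category_distribution_stats(
                cat_table,
                n_draws=config.n_session_draws,
                draw_size=config.session_draw_size,
                seed=stage_seed(config.seed, "category_stats"),
            )
            with open(out_dir / "category_stats.json", "w") as fh:
                json.dump(stats, fh, indent=1)
            report["category_stats"] = stats
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report


def select_session_per_neuron(
    table: pd.DataFrame, seed: int = 0, perturbation: bool = False
) -> pd.DataFrame:
    """One row per neuron for population summaries.

    Neurons imaged in several sessions contribute once: a seeded random
    session in general, or the session with the largest |perturbation P|
    when summarizing perturbation responses.
    """
    if not {"neuron", "session"}.issubset(table.columns):
        raise ValueError("table needs neuron and session columns")
    rng = np.random.default_rng(seed)
    picks = []
    for _, grp in table.groupby("neuron"):
        if perturbation and "perturbation_P" in grp:
            with np.errstate(invalid="ignore"):
                idx = grp["perturbation_P"].abs().fillna(-np.inf).idxmax()
        else:
            idx = grp.index[rng.integers(len(grp))]
        picks.append(idx)
    return table.loc[picks].reset_index(drop=True)
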