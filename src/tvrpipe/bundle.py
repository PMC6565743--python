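"""Session container and on-disk format.

A session bundle holds every synchronized stream of one imaging session:
raw fluorescence per ROI at the 10-Hz imaging rate, treadmill run speed at
40 Hz, mean whisker angle at 200 Hz, and the per-frame texture flags
(texture-rotation speed, whisker contact, linear-stage motion, perturbation)
at 10 Hz, together with trial boundaries and metadata.  Synthetic sessions
additionally carry their generative ground truth.

On disk a session is a directory of plain-text files::

    meta.json          rates, condition, layer, seed
    behavior_40hz.csv  time_s, run_speed
    whisker_200hz.csv  time_s, angle_deg
    frames_10hz.csv    time_s, texture_speed, contact, stage_moving, perturbation
    fluo_10hz.csv      time_s, roi_000, roi_001, ...
    trials.csv         start_s, end_s
    ground_truth.json  synthetic sessions only

Times are seconds (float), frame indices 0-based, trial intervals half-open
[start, end).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import IMAGING_RATE_HZ, SPEED_RATE_HZ, WHISKER_RATE_HZ

REQUIRED_FILES = (
    "meta.json",
    "behavior_40hz.csv",
    "whisker_200hz.csv",
    "frames_10hz.csv",
    "fluo_10hz.csv",
    "trials.csv",
)


@dataclass
class SessionBundle:
    run_speed: np.ndarray            # cm/s at 40 Hz
    whisker_angle: np.ndarray        # degrees at 200 Hz
    texture_speed: np.ndarray        # cm/s at 10 Hz
    contact_flag: np.ndarray         # binary at 10 Hz
    stage_moving_flag: np.ndarray    # binary at 10 Hz
    perturbation_flag: np.ndarray    # binary at 10 Hz
    trial_intervals: list[tuple[float, float]]
    meta: dict = field(default_factory=dict)
    fluo: np.ndarray | None = None   # ROI x frame raw fluorescence at 10 Hz
    ground_truth: dict | None = None

    @property
    def n_frames(self) -> int:
        return len(self.texture_speed)

    @property
    def duration_s(self) -> float:
        return self.n_frames / IMAGING_RATE_HZ

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / IMAGING_RATE_HZ

    @property
    def n_neurons(self) -> int:
        return 0 if self.fluo is None else self.fluo.shape[0]

    def validate(self) -> None:
        n10 = self.n_frames
        checks = {
            "behavior_40hz": (len(self.run_speed), int(round(n10 * SPEED_RATE_HZ / IMAGING_RATE_HZ))),
            "whisker_200hz": (len(self.whisker_angle), int(round(n10 * WHISKER_RATE_HZ / IMAGING_RATE_HZ))),
            "contact_flag": (len(self.contact_flag), n10),
            "stage_moving_flag": (len(self.stage_moving_flag), n10),
            "perturbation_flag": (len(self.perturbation_flag), n10),
        }
        for name, (got, want) in checks.items():
            if got != want:
                raise ValueError(
                    f"stream '{name}' spans {got} samples, expected {want} "
                    f"for {n10} imaging frames (misaligned streams)"
                )
        if self.fluo is not None and self.fluo.shape[1] != n10:
            raise ValueError(
                f"fluorescence has {self.fluo.shape[1]} frames, expected {n10}"
            )
        if self.contact_flag.any() and self.meta.get("condition") == "no_touch":
            raise ValueError("contact_flag set in a no_touch session")
        for start, end in self.trial_intervals:
            if end <= start:
                raise ValueError(f"empty trial interval ({start}, {end})")

    # -- per-stream time axes -------------------------------------------------
    def speed_times(self) -> np.ndarray:
        return np.arange(len(self.run_speed)) / SPEED_RATE_HZ

    def whisker_times(self) -> np.ndarray:
        return np.arange(len(self.whisker_angle)) / WHISKER_RATE_HZ

    def trial_index_of_frames(self) -> np.ndarray:
        """Trial id per imaging frame, -1 during inter-trial intervals."""
        t = self.frame_times
        out = np.full(self.n_frames, -1, dtype=int)
        for i, (s, e) in enumerate(self.trial_intervals):
            out[(t >= s) & (t < e)] = i
        return out


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "meta.json", "w") as fh:
        json.dump(
            {
                "imaging_rate_hz": IMAGING_RATE_HZ,
                "speed_rate_hz": SPEED_RATE_HZ,
                "whisker_rate_hz": WHISKER_RATE_HZ,
                **bundle.meta,
            },
            fh,
            indent=1,
        )
    pd.DataFrame(
        {"time_s": bundle.speed_times(), "run_speed": bundle.run_speed}
    ).to_csv(path / "behavior_40hz.csv", index=False)
    pd.DataFrame(
        {"time_s": bundle.whisker_times(), "angle_deg": bundle.whisker_angle}
    ).to_csv(path / "whisker_200hz.csv", index=False)
    pd.DataFrame(
        {
            "time_s": bundle.frame_times,
            "texture_speed": bundle.texture_speed,
            "contact": bundle.contact_flag.astype(int),
            "stage_moving": bundle.stage_moving_flag.astype(int),
            "perturbation": bundle.perturbation_flag.astype(int),
        }
    ).to_csv(path / "frames_10hz.csv", index=False)
    fluo_cols = {"time_s": bundle.frame_times}
    if bundle.fluo is not None:
        for i, row in enumerate(bundle.fluo):
            fluo_cols[f"roi_{i:03d}"] = row
    pd.DataFrame(fluo_cols).to_csv(path / "fluo_10hz.csv", index=False)
    pd.DataFrame(bundle.trial_intervals, columns=["start_s", "end_s"]).to_csv(
        path / "trials.csv", index=False
    )
    if bundle.ground_truth is not None:
        with open(path / "ground_truth.json", "w") as fh:
            json.dump(_jsonable(bundle.ground_truth), fh)
    return path


def read_session(path: str | Path) -> SessionBundle:
    path = Path(path)
    for name in REQUIRED_FILES:
        if not (path / name).exists():
            raise FileNotFoundError(f"session at {path} is missing required file '{name}'")
    with open(path / "meta.json") as fh:
        meta = json.load(fh)
    for key, expected in (
        ("imaging_rate_hz", IMAGING_RATE_HZ),
        ("speed_rate_hz", SPEED_RATE_HZ),
        ("whisker_rate_hz", WHISKER_RATE_HZ),
    ):
        if key in meta and meta[key] != expected:
            raise ValueError(f"{path}/meta.json declares {key}={meta[key]}, expected {expected}")
    behavior = pd.read_csv(path / "behavior_40hz.csv", float_precision="round_trip")
    whisker = pd.read_csv(path / "whisker_200hz.csv", float_precision="round_trip")
    frames = pd.read_csv(path / "frames_10hz.csv", float_precision="round_trip")
    fluo_df = pd.read_csv(path / "fluo_10hz.csv", float_precision="round_trip")
    trials = pd.read_csv(path / "trials.csv", float_precision="round_trip")
    roi_cols = [c for c in fluo_df.columns if c.startswith("roi_")]
    fluo = fluo_df[roi_cols].to_numpy().T if roi_cols else None
    gt = None
    if (path / "ground_truth.json").exists():
        with open(path / "ground_truth.json") as fh:
            gt = json.load(fh)
    bundle = SessionBundle(
        run_speed=behavior["run_speed"].to_numpy(float),
        whisker_angle=whisker["angle_deg"].to_numpy(float),
        texture_speed=frames["texture_speed"].to_numpy(float),
        contact_flag=frames["contact"].to_numpy(int),
        stage_moving_flag=frames["stage_moving"].to_numpy(int),
        perturbation_flag=frames["perturbation"].to_numpy(int),
        trial_intervals=[(float(s), float(e)) for s, e in zip(trials["start_s"], trials["end_s"])],
        meta=meta,
        fluo=fluo,
        ground_truth=gt,
    )
    bundle.validate()
    return bundle


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
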