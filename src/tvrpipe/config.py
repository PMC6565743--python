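"""Pipeline-wide configuration.

All analysis thresholds and windows live here with their published defaults
(whisking std threshold 2.5 deg, running threshold 0.8 cm/s, 400-ms onset
bout minima, touch analysis windows, the 2-sigma responsiveness criteria,
ANOVA alpha 1e-3, explained-variance floor 0.30, 100 bootstrap replicates,
200-ms calcium delay for mutual information, 32-tree / min-leaf-10 forest
with +/-300-ms shifts, 2-s test chunks, 5 repeats).  Overriding any field is
supported but the override is recorded into every report this config touches.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

IMAGING_RATE_HZ = 10.0
SPEED_RATE_HZ = 40.0
WHISKER_RATE_HZ = 200.0


@dataclass
class PipelineConfig:
    # behavioral-state segmentation
    whisk_std_window: int = 51          # samples at 200 Hz for the sliding std
    whisk_std_threshold_deg: float = 2.5
    run_gauss_fwhm_s: float = 1.0       # first smoothing stage of run speed
    run_savgol_window_s: float = 1.1    # second stage, 1st-order Savitzky-Golay
    run_threshold_cms: float = 0.8
    # event detection
    min_off_s: float = 0.4
    min_on_s: float = 0.4
    onset_pre_s: float = 2.0
    event_smooth_window_s: float = 0.5  # 1st-order Savitzky-Golay on averages
    touch_pre_window: tuple[float, float] = (-1.0, -0.3)
    touch_early_window: tuple[float, float] = (0.3, 1.3)
    touch_late_window: tuple[float, float] = (2.0, 3.0)
    perturb_post_window: tuple[float, float] = (0.3, 2.0)
    touch_context_window: tuple[float, float] = (-1.0, 4.0)
    touch_run_speed_cms: float = 2.0    # mean speed above -> touch during running
    touch_rest_speed_cms: float = 1.0   # mean speed below -> touch during resting
    perturb_run_speed_cms: float = 2.0
    responsive_sigma_factor: float = 2.0
    # speed tuning
    n_speed_bins: int = 10
    stationary_speed_cms: float = 1.0
    anova_alpha: float = 1e-3
    tuning_train_fraction: float = 0.8
    tuning_ev_floor: float = 0.30
    tuning_n_starts: int = 5
    # functional classification
    n_bootstrap: int = 100
    n_session_draws: int = 10
    session_draw_size: int = 11
    # mutual information
    mi_max_shift_ms: float = 1000.0
    mi_shift_step_ms: float = 100.0
    mi_analysis_delay_ms: float = 200.0
    mi_fd_coefficient: float = 2.5
    mi_min_condition_fraction: float = 0.10
    # encoding model
    rf_n_trees: int = 32
    rf_min_leaf: int = 10
    encoding_max_shift_frames: int = 3  # +/-300 ms at 10 Hz
    encoding_test_fraction: float = 0.2
    encoding_chunk_s: float = 2.0
    encoding_n_repeats: int = 5
    # global
    seed: int = 0

    def override(self, **kwargs) -> "PipelineConfig":
        """Return a copy with fields replaced; remembers what changed."""
        new = dataclasses.replace(self, **kwargs)
        new._overrides = {**getattr(self, "_overrides", {}), **kwargs}
        return new

    @property
    def overrides(self) -> dict:
        return dict(getattr(self, "_overrides", {}))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["_overrides"] = self.overrides
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix in {".yaml", ".yml"}:
                raw = yaml.safe_load(fh) or {}
            else:
                raw = json.load(fh)
        raw.pop("_overrides", None)
        base = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        # YAML/JSON round-trips tuples as lists
        for f in dataclasses.fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return base.override(**raw) if raw else base


def _mix_seed(*parts) -> int:
    """Derive a deterministic 31-bit seed from (global seed, stage, session...)."""
    import zlib

    key = "|".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def stage_seed(config_seed: int, stage: str, session_id: str = "") -> int:
    return _mix_seed(config_seed, stage, session_id)
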