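#!/usr/bin/env python
"""Run the full analysis pipeline over the simulated cohort.

Executes preprocess -> segment -> respond -> tuning -> classify -> mi ->
encode for every session in scratch/cohort/ and writes the per-session
stage tables plus the cohort report under results/pipeline/.
"""

import sys
from pathlib import Path

from tvrpipe.config import PipelineConfig
from tvrpipe.pipeline import run_pipeline

COHORT = Path("scratch/cohort")
OUT = Path("results/pipeline")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main():
    sessions = sorted(p for p in COHORT.iterdir() if p.is_dir())
    if not sessions:
        raise SystemExit("no sessions found; run analysis/01_simulate_cohort.py first")
    report = run_pipeline(PipelineConfig(seed=SEED), sessions, OUT)
    print(f"pipeline over {len(report['sessions'])} sessions -> {OUT}/report.json")
    for sid, s in report["sessions"].items():
        print(f"  {sid}: stages {', '.join(s['stages_run'])}")
    if report["errors"]:
        print(f"  errors: {list(report['errors'])}")


if __name__ == "__main__":
    main()
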