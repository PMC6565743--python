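#!/usr/bin/env python
"""Ground-truth recovery checks for the whole pipeline.

Runs the validation suite on freshly generated synthetic data: the analytic
11-21 Hz rate-conversion bounds, onset-detector oracle agreement, mutual-
information estimator sanity, category / speed-tuning / encoding recovery,
forward-model consistency, suppression separation, and the sound-control
false-positive rate.  Writes results/recovery_checks.json.

This is the same computation as scripts/acceptance.py; run that script for
a reproducible single-command version.
"""

import json
import sys
import warnings
from pathlib import Path

import tvrpipe.validation as v

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/recovery_checks.json")


def main():
    warnings.filterwarnings("ignore")
    checks = {
        "rate_conversion": v.rate_conversion_bounds(),
        "onset_oracle": v.onset_oracle_agreement(SEED),
        "mi_estimator": v.mi_estimator_checks(SEED),
        "category_recovery": v.category_recovery(SEED),
        "tuning_recovery": v.tuning_recovery(SEED),
        "encoding_recovery": v.encoding_recovery(SEED),
        "steady_state": v.steady_state_consistency(SEED),
        "suppression": v.suppression_recovery(SEED),
        "sound_control": v.control_false_positive_rate(SEED),
    }
    OUT.parent.mkdir(parents=True, exist_ok=True)
    OUT.write_text(json.dumps(checks, indent=1))
    print(json.dumps(checks, indent=1))
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
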