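#!/usr/bin/env python
"""Generate the synthetic session cohort used by the downstream analyses.

Builds 12 sessions (6 per cortical layer label) across the three behavioral
conditions — closed loop, open loop (with texture-halt perturbations), and
the no-touch sound control — each with a mixed population of rest-, run-,
touch- and integrative-type neurons plus speed-tuned and noise cells, and
writes them as plain-text session bundles under scratch/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

from tvrpipe.bundle import write_session
from tvrpipe.synth import BehaviorConfig, NeuronSpec, generate_behavior, generate_fluorescence

OUT = Path("scratch/cohort")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

CONDITIONS = ["closed_loop", "open_loop", "open_loop", "no_touch"]


def neuron_population(rng, n=24):
    cats = ["rest", "run", "touch", "integrative"]
    specs = [NeuronSpec.make(cats[i % 4], rng) for i in range(n - 4)]
    # a couple of band-pass speed-tuned cells and noise cells per session
    for _ in range(2):
        specs.append(
            NeuronSpec.make("run", rng, speed_tuning=(rng.uniform(4, 12), 8.0, 8.0))
        )
    specs += [NeuronSpec.make("noise", rng) for _ in range(2)]
    return specs


def main():
    rng = np.random.default_rng(SEED)
    n_sessions = 0
    for layer in ("L2/3", "L5"):
        for j, condition in enumerate(CONDITIONS + CONDITIONS[:2]):
            sid = f"{layer.replace('/', '')}_{condition}_{j}"
            cfg = BehaviorConfig(
                n_trials=25,
                condition=condition,
                layer=layer,
                rng_seed=int(rng.integers(2**31)),
            )
            behavior = generate_behavior(cfg)
            specs = neuron_population(np.random.default_rng(rng.integers(2**31)))
            session = generate_fluorescence(behavior, specs, int(rng.integers(2**31)))
            write_session(session, OUT / sid)
            n_sessions += 1
            print(f"{sid}: {session.n_neurons} neurons, {session.duration_s:.0f} s, "
                  f"{int(np.sum(session.contact_flag))} contact frames")
    print(f"\nwrote {n_sessions} sessions to {OUT}/")


if __name__ == "__main__":
    main()
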