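#!/usr/bin/env python
"""Generate the two synthetic experiments the downstream analyses consume.

Writes tidy trial CSVs for the dichoptic-suppression arm (U-shaped
congruence-effect profile, 36 participants x 192 trials) and the monocular
control arm (decaying profile) under results/.
"""

import argparse
import dataclasses
from pathlib import Path

from cfsbias.simulate import load_preset, simulate_experiment, write_trials

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    RESULTS.mkdir(exist_ok=True)
    for preset in ("exp1", "exp2"):
        spec, profile = load_preset(preset)
        spec = dataclasses.replace(spec, seed=args.seed)
        trials = simulate_experiment(spec, profile)
        out = RESULTS / f"trials_{preset}.csv"
        write_trials(trials, out)
        print(f"{preset}: {len(trials)} trials, {spec.n_participants} participants, "
              f"timeout rate {trials['timed_out'].mean():.3%} -> {out}")


if __name__ == "__main__":
    main()
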