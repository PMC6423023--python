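#!/usr/bin/env python
"""Operating characteristics of the Bayesian optional-stopping rule.

Simulates the sequential design (test until both the repetition-1 and
repetition-6 directional BFs cross 6 or 1/6, minimum 20 participants) under
a zero-effect profile and under a strong-effect profile, and summarizes stop
sample sizes and decision rates.  Replicate counts are kept modest here; the
test suite runs the larger calibration.
"""

import argparse
import dataclasses
import json
from pathlib import Path

import pandas as pd

from cfsbias.simulate import load_preset
from cfsbias.stopping import StoppingRule, simulate_stopping

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-sims", type=int, default=40)
    args = ap.parse_args()

    spec, null_profile = load_preset("null")
    strong = dataclasses.replace(null_profile,
                                 delta=(0.15, 0.0, 0.0, 0.0, 0.0, 0.15),
                                 base_rt_cv=0.15)
    out = {}
    for name, profile, rule in [
        ("null", null_profile, StoppingRule(max_n=100)),
        ("strong_effect", strong, StoppingRule(max_n=60)),
    ]:
        traces, summary = simulate_stopping(rule, profile, args.n_sims,
                                            seed=args.seed, spec=spec)
        out[name] = summary
        pd.DataFrame([{"seed": t.seed, "final_n": t.final_n,
                       "decision": t.decision} for t in traces]).to_csv(
            RESULTS / f"stopping_{name}.csv", index=False)
        print(f"{name}: decisions {summary['decision_rates']}, "
              f"median stop N {summary['final_n_quantiles'][0.5]:.0f}")
    (RESULTS / "stopping_summary.json").write_text(
        json.dumps(out, indent=2, default=float))


if __name__ == "__main__":
    main()
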