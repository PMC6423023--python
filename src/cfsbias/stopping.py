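"""Bayesian optional-stopping design: rule evaluation and Monte Carlo simulation.

Sampling continues until the directional Bayes factors for BOTH monitored
tests (the repetition-1 and repetition-6 congruence effects) are conclusive —
each either above ``bf_upper`` (default 6, evidence for faster matching
responses) or below ``bf_lower`` (default 1/6, evidence for no effect) — with
a minimum number of participants (default 20).  Both tests must be
individually conclusive, possibly in different directions ("mixed").  A
safety cap ``max_n`` bounds simulations; the original design has no cap.

``simulate_stopping`` characterizes the rule's operating characteristics
(stop-N distribution, decision rates) under a configurable true effect
profile by growing a simulated experiment participant by participant and
re-testing at every look.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import jzs_bf_one_sample, one_sample_t
from .design import DesignSpec
from .preprocess import normalized_effects
from .simulate import EffectProfile, simulate_participant

MONITORED_REPS = (1, 6)


@dataclass(frozen=True)
class StoppingRule:
    bf_upper: float = 6.0
    bf_lower: float = 1.0 / 6.0
    min_n: int = 20
    batch: int = 1
    max_n: int = 100
    r: float = 0.707

    def __post_init__(self):
        if self.min_n < 2:
            raise ValueError("min_n must be >= 2")
        if self.max_n < self.min_n:
            raise ValueError("max_n must be >= min_n")
        if not (0 < self.bf_lower < 1 < self.bf_upper):
            raise ValueError("need bf_lower < 1 < bf_upper")


@dataclass
class StoppingTrace:
    """One simulated sequential experiment."""

    looks: pd.DataFrame          # columns: n, bf_rep1, bf_rep6
    final_n: int
    decision: str                # alternative | null | mixed | cap_reached
    seed: int


def _boundary(bf: float, rule: StoppingRule):
    if bf >= rule.bf_upper:
        return "alternative"
    if bf <= rule.bf_lower:
        return "null"
    return None


def evaluate_stop(bf1: float, bf6: float, n: int, rule: StoppingRule):
    """Stop decision at one look: ``(stop, decision)``.

    Stops iff ``n >= min_n`` and both monitored BFs are conclusive; the
    decision is 'alternative' or 'null' when the two tests agree, 'mixed'
    when they hit opposite boundaries.
    """
    if bf1 <= 0 or bf6 <= 0:
        raise ValueError("Bayes factors must be positive")
    if n < rule.min_n:
        return False, None
    b1, b6 = _boundary(bf1, rule), _boundary(bf6, rule)
    if b1 is None or b6 is None:
        return False, None
    return True, (b1 if b1 == b6 else "mixed")


def _participant_d(spec: DesignSpec, profile: EffectProfile,
                   rng: np.random.Generator, pid: int):
    """(d_rep1, d_rep6) for one freshly simulated participant."""
    trials = simulate_participant(spec, profile, rng, participant_id=pid)
    eff = normalized_effects(trials, by_repetition=True)
    eff = eff.set_index("repetition")["d"]
    return float(eff.loc[MONITORED_REPS[0]]), float(eff.loc[MONITORED_REPS[1]])


def run_sequential(rule: StoppingRule, spec: DesignSpec, profile: EffectProfile,
                   seed: int) -> StoppingTrace:
    """Run one sequential experiment under the rule; reproducible from seed."""
    streams = np.random.SeedSequence(seed).spawn(rule.max_n)
    d1, d6, looks = [], [], []
    decision, final_n = "cap_reached", rule.max_n
    n = 0
    while n < rule.max_n:
        take = min(rule.batch, rule.max_n - n) if n >= rule.min_n else rule.min_n
        for _ in range(take):
            a, b = _participant_d(spec, profile, np.random.default_rng(streams[n]), n)
            d1.append(a)
            d6.append(b)
            n += 1
        bf1 = jzs_bf_one_sample(*one_sample_t(d1), r=rule.r, direction="positive").bf
        bf6 = jzs_bf_one_sample(*one_sample_t(d6), r=rule.r, direction="positive").bf
        looks.append({"n": n, "bf_rep1": bf1, "bf_rep6": bf6})
        stop, dec = evaluate_stop(bf1, bf6, n, rule)
        if stop:
            decision, final_n = dec, n
            break
    return StoppingTrace(looks=pd.DataFrame(looks), final_n=final_n,
                         decision=decision, seed=seed)


def simulate_stopping(rule: StoppingRule, profile: EffectProfile, n_sims: int,
                      seed: int, spec: DesignSpec | None = None):
    """Monte Carlo operating characteristics of the stopping rule.

    Returns ``(traces, summary)`` where ``summary`` holds decision rates and
    the stop-N distribution.  Raises if more than half of the replicates hit
    the safety cap (an uninformative configuration).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    spec = spec or DesignSpec()
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_sims) % (2**31)
    traces = [run_sequential(rule, spec, profile, int(s)) for s in rep_seeds]

    decisions = pd.Series([t.decision for t in traces])
    rates = (decisions.value_counts() / n_sims).to_dict()
    summary = {
        "n_sims": n_sims,
        "decision_rates": {k: rates.get(k, 0.0)
                           for k in ("alternative", "null", "mixed", "cap_reached")},
        "final_n_mean": float(np.mean([t.final_n for t in traces])),
        "final_n_quantiles": {q: float(np.quantile([t.final_n for t in traces], q))
                              for q in (0.1, 0.5, 0.9)},
        "stopped_at_min_n_rate": float(np.mean([t.final_n == rule.min_n for t in traces])),
    }
    if summary["decision_rates"]["cap_reached"] > 0.5:
        raise RuntimeError(
            "more than half of replicates hit max_n: the configuration is "
            "uninformative for this rule"
        )
    return traces, summary
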