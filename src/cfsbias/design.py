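"""Counterbalanced trial-design builder for repeated-memorization b-CFS experiments.

The experiment is organized as a series of sequences of consecutive trials in
which the same item is held in memory ("repetitions").  Within a sequence the
cued and discarded color categories are fixed; congruence (whether the target
matches the cued or the discarded category), retro-cue and target hemifield
vary trial-by-trial under exact experiment-level counterbalancing:

* every Congruence x Repetition cell occurs exactly ``n_sequences / 2`` times,
* every color category is cued on the same number of sequences,
* consecutive sequences never share a cued category.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of the tidy trial table (design skeleton + response fields)
TRIAL_COLUMNS = [
    "participant_id",
    "arm",
    "sequence_index",
    "repetition",
    "congruence",
    "cued_category",
    "discarded_category",
    "retro_cue",
    "hemifield",
    "rt_ms",
    "localization_correct",
    "recognition_correct",
    "timed_out",
]

DEFAULT_COLOR_PAIRS = (("red", "blue"), ("green", "purple"))


class DesignError(ValueError):
    """Raised when a design specification is infeasible."""


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of the factorial repeated-memorization design.

    Defaults reproduce the canonical layout: 36 participants, 32 six-trial
    sequences (192 trials) per participant in 12 blocks, targets censored at
    5 s, target onset jittered 300-600 ms after mask onset (the response clock
    starts at target-ramp onset, so the jitter never enters ``rt_ms``).
    """

    n_participants: int = 36
    n_sequences: int = 32
    reps_per_sequence: int = 6
    n_blocks: int = 12
    arm: str = "suppression"  # "suppression" (dichoptic) or "monocular"
    color_pairs: tuple = DEFAULT_COLOR_PAIRS
    max_rt: float = 5000.0
    onset_jitter: tuple = (300.0, 600.0)
    seed: int = 0

    def __post_init__(self):
        if self.arm not in ("suppression", "monocular"):
            raise DesignError(f"unknown arm {self.arm!r}")
        if self.reps_per_sequence < 2 or self.reps_per_sequence % 2:
            raise DesignError(
                "reps_per_sequence must be even and >= 2 for exact "
                "congruence balance within sequences"
            )
        if self.n_sequences < 2 or self.n_sequences % 2:
            raise DesignError("n_sequences must be even and >= 2")
        cats = self.categories
        if len(cats) != len(set(cats)):
            raise DesignError("color categories must be distinct")
        if len(cats) < 2:
            raise DesignError(
                "need at least 2 categories for the no-consecutive-category "
                "constraint to be satisfiable"
            )
        if self.n_sequences % len(cats):
            raise DesignError(
                f"n_sequences={self.n_sequences} not divisible by the "
                f"{len(cats)} color categories"
            )
        if self.max_rt <= 0:
            raise DesignError("max_rt must be positive")

    @property
    def categories(self) -> tuple:
        return tuple(itertools.chain.from_iterable(self.color_pairs))

    @property
    def n_trials(self) -> int:
        return self.n_sequences * self.reps_per_sequence

    @property
    def partner(self) -> dict:
        """Category -> paired (discarded) category, both directions."""
        out = {}
        for a, b in self.color_pairs:
            out[a], out[b] = b, a
        return out


def _category_order(spec: DesignSpec, rng: np.random.Generator) -> list:
    """Cued category per sequence: balanced counts, no immediate repeats."""
    cats = list(spec.categories)
    per_cat = spec.n_sequences // len(cats)
    for _ in range(10_000):
        remaining = {c: per_cat for c in cats}
        order, prev, dead = [], None, False
        for _ in range(spec.n_sequences):
            allowed = [c for c in cats if remaining[c] > 0 and c != prev]
            if not allowed:
                dead = True
                break
            slots_left = sum(remaining.values())
            # a category holding a strict majority of remaining slots is forced
            forced = [c for c in allowed if 2 * remaining[c] > slots_left]
            pick = forced[0] if forced else allowed[rng.integers(len(allowed))]
            order.append(pick)
            remaining[pick] -= 1
            prev = pick
        if not dead:
            return order
    raise DesignError("could not order sequences without consecutive repeats")


def _congruence_patterns(spec: DesignSpec, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_sequences, reps) match indicator, column sums n_sequences/2.

    Each sequence holds exactly half match / half mismatch trials; sequences
    are drawn in pattern/complement pairs so each repetition position is
    matched on exactly half of the sequences, then shuffled.
    """
    reps = spec.reps_per_sequence
    half = spec.n_sequences // 2
    pats = np.zeros((spec.n_sequences, reps), dtype=bool)
    for i in range(half):
        idx = rng.choice(reps, size=reps // 2, replace=False)
        pats[2 * i, idx] = True
        pats[2 * i + 1] = ~pats[2 * i]
    rng.shuffle(pats, axis=0)
    return pats


def _balanced_factor_pairs(n: int, rng: np.random.Generator) -> np.ndarray:
    """n rows of (retro_cue, hemifield) with all 4 combinations near-equal."""
    combos = np.array([(1, 0), (1, 1), (2, 0), (2, 1)])
    tiled = np.tile(combos, (n // 4 + 1, 1))[:n]
    rng.shuffle(tiled, axis=0)
    return tiled


def build_design(
    spec: DesignSpec,
    rng: np.random.Generator | None = None,
    participant_id: int = 0,
) -> pd.DataFrame:
    """Build one participant's ordered trial skeleton (no responses).

    Returns a DataFrame with ``TRIAL_COLUMNS``; the response fields
    (``rt_ms``, correctness, ``timed_out``) are left missing.  Reproducible
    from ``spec.seed`` when no generator is passed.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    cued = _category_order(spec, rng)
    partner = spec.partner
    match = _congruence_patterns(spec, rng)

    n = spec.n_trials
    reps = spec.reps_per_sequence
    df = pd.DataFrame(
        {
            "participant_id": participant_id,
            "arm": spec.arm,
            "sequence_index": np.repeat(np.arange(spec.n_sequences), reps),
            "repetition": np.tile(np.arange(1, reps + 1), spec.n_sequences),
            "congruence": np.where(match.ravel(), "match", "mismatch"),
            "cued_category": np.repeat(cued, reps),
        }
    )
    df["discarded_category"] = df["cued_category"].map(partner)

    # counterbalance retro-cue and hemifield within each congruence x
    # repetition cell (the factors of interest)
    df["retro_cue"] = 0
    df["hemifield"] = ""
    for _, idx in df.groupby(["congruence", "repetition"], sort=False).groups.items():
        fac = _balanced_factor_pairs(len(idx), rng)
        df.loc[idx, "retro_cue"] = fac[:, 0]
        df.loc[idx, "hemifield"] = np.where(fac[:, 1] == 0, "left", "right")

    df["rt_ms"] = np.nan
    df["localization_correct"] = pd.array([pd.NA] * n, dtype="boolean")
    df["recognition_correct"] = pd.array([pd.NA] * n, dtype="boolean")
    df["timed_out"] = pd.array([pd.NA] * n, dtype="boolean")
    return df[TRIAL_COLUMNS]
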