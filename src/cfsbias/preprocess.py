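"""Trial filtering, condition medians, and the latency-normalized RT effect.

The headline statistic is the latency-normalized response-time difference

    d = (median_mismatch - median_match) / ((median_match + median_mismatch) / 2)

computed per participant (optionally per repetition).  Positive ``d`` means
faster responses to memory-matching targets.  Normalizing by the mean of the
two condition medians removes between-subject variance in absolute RT and
yields approximately normal per-participant effects, so parametric tests can
be applied downstream; normality is checked per repetition with Shapiro-Wilk.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class EmptyCellError(ValueError):
    """A participant x repetition x congruence cell lost all its trials."""


def filter_trials(trials: pd.DataFrame):
    """Drop timeout and localization-error trials before any RT analysis.

    Returns ``(kept, report)`` where ``report`` counts excluded trials per
    participant.  Raises :class:`EmptyCellError` if filtering empties any
    participant x repetition x congruence cell, naming the cell.
    """
    timeouts = trials["timed_out"].fillna(False).astype(bool)
    errors = ~trials["localization_correct"].fillna(False).astype(bool) & ~timeouts
    kept = trials[~timeouts & ~errors].copy()

    report = (
        pd.DataFrame(
            {
                "participant_id": trials["participant_id"],
                "timeout": timeouts.astype(int),
                "localization_error": errors.astype(int),
            }
        )
        .groupby("participant_id", as_index=False)
        .sum()
    )
    report["excluded"] = report["timeout"] + report["localization_error"]

    counts = kept.groupby(["participant_id", "repetition", "congruence"]).size()
    full = pd.MultiIndex.from_product(
        [
            trials["participant_id"].unique(),
            trials["repetition"].unique(),
            trials["congruence"].unique(),
        ],
        names=["participant_id", "repetition", "congruence"],
    )
    empty = full.difference(counts.index)
    if len(empty):
        pid, rep, cong = empty[0]
        raise EmptyCellError(
            f"participant {pid}: no trials left in repetition {rep} / "
            f"{cong} cell after filtering"
        )
    return kept, report


def condition_medians(trials: pd.DataFrame, by_repetition: bool = True) -> pd.DataFrame:
    """Median RT per participant x congruence (x repetition).

    Medians use the midpoint convention for even cell counts (numpy default).
    With ``by_repetition=False`` trials are pooled over repetitions first and
    the ``repetition`` column holds ``"all"``.
    """
    keys = ["participant_id", "arm"]
    if by_repetition:
        keys.append("repetition")
    g = trials.groupby(keys + ["congruence"])["rt_ms"]
    med = g.median().unstack("congruence")
    cnt = g.size().unstack("congruence")
    out = med.rename(columns={"match": "median_match", "mismatch": "median_mismatch"})
    out["n_trials_match"] = cnt["match"]
    out["n_trials_mismatch"] = cnt["mismatch"]
    out = out.reset_index()
    if not by_repetition:
        out.insert(2, "repetition", "all")
    out.columns.name = None
    return out


def latency_normalized_difference(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-participant latency-normalized effect ``d`` from condition medians.

    Raises on non-positive medians (``d`` is only defined for positive RTs);
    the formula bounds ``d`` to (-2, 2).
    """
    m, mm = summary["median_match"], summary["median_mismatch"]
    if (m <= 0).any() or (mm <= 0).any():
        raise ValueError("condition medians must be positive")
    out = summary[["participant_id", "arm", "repetition"]].copy()
    out["d"] = (mm - m) / ((m + mm) / 2.0)
    out["mean_median_rt"] = (m + mm) / 2.0
    return out


def normalized_effects(trials: pd.DataFrame, by_repetition: bool = True) -> pd.DataFrame:
    """Convenience: filter -> condition medians -> normalized effects."""
    kept, _ = filter_trials(trials)
    return latency_normalized_difference(condition_medians(kept, by_repetition=by_repetition))


def normality_check(effects: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Shapiro-Wilk normality diagnostics of ``d`` per repetition.

    Requires at least 3 participants per repetition; a constant sample leaves
    W undefined and is flagged ``degenerate`` instead of tested.
    """
    rows = []
    for rep, grp in effects.groupby("repetition", sort=False):
        x = grp["d"].to_numpy(dtype=float)
        if x.size < 3:
            raise ValueError(f"repetition {rep!r}: need >= 3 participants, got {x.size}")
        if np.ptp(x) == 0:
            rows.append({"repetition": rep, "W": np.nan, "p": np.nan,
                         "violated": False, "degenerate": True})
            continue
        w, p = stats.shapiro(x)
        rows.append({"repetition": rep, "W": w, "p": p,
                     "violated": p < alpha, "degenerate": False})
    return pd.DataFrame(rows)
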