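"""End-to-end analysis of a tidy trial table.

``run_analysis`` executes the full chain on one or two experiment arms:
filter -> condition medians -> latency normalization -> per-repetition and
overall directional Bayes factors -> between-arm comparisons (two arms) ->
AIC model comparison on the congruence-effect and recognition profiles ->
recognition-vs-chance test -> localization summary.  No multiple-comparison
correction is applied: Bayes factors quantify evidence per test, consecutive
repetitions are not independent, and the profile-level model comparison
adjudicates the overall progression explicitly.

Bayes factors below 1 are additionally reported in reciprocal ("BF_0+")
style, the conventional way of stating evidence *for* the null.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .bayes import (bf_from_effects, jzs_bf_one_sample, jzs_bf_two_sample,
                    one_sample_t, t_from_two_summaries)
from .models import compare_families, fits_table
from .preprocess import (condition_medians, filter_trials,
                         latency_normalized_difference, normality_check)

REQUIRED_COLUMNS = [
    "participant_id", "arm", "repetition", "congruence", "rt_ms",
    "localization_correct", "recognition_correct", "timed_out",
]


@dataclass
class AnalysisReport:
    """All result tables of one pipeline run, serializable to CSV/JSON."""

    per_repetition: pd.DataFrame          # per arm x repetition effect + BF
    overall: pd.DataFrame                 # per arm pooled effect + BF
    between_arms: pd.DataFrame | None     # two-sample BFs (two-arm input only)
    model_comparison: pd.DataFrame        # AIC table per arm x outcome
    recognition: pd.DataFrame             # accuracy + BF vs 50% chance, per arm
    localization: pd.DataFrame            # accuracy summary per arm
    normality: pd.DataFrame               # Shapiro-Wilk diagnostics per arm
    provenance: dict

    def to_dict(self) -> dict:
        out = {k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
               for k, v in self.__dict__.items() if v is not None}
        return out

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("per_repetition", "overall", "between_arms",
                     "model_comparison", "recognition", "localization", "normality"):
            df = getattr(self, name)
            if df is not None:
                df.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, default=float))


def _bf_row(d: np.ndarray):
    res = bf_from_effects(d, direction="positive")
    return {
        "mean_d": float(np.mean(d)),
        "sd_d": float(np.std(d, ddof=1)),
        "t": res.t,
        "n": int(res.n_eff),
        "bf_plus": res.bf,
        "bf_null": res.bf_null,
        "log_bf": res.log_bf,
        "evidence": res.evidence,
    }


def validate_trials(trials: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    bad = trials.index[~trials["congruence"].isin(["match", "mismatch"])]
    if len(bad):
        raise ValueError(f"invalid congruence labels at rows {list(bad[:5])}")
    bad = trials.index[~trials["repetition"].between(1, 6)]
    if len(bad):
        raise ValueError(f"repetition outside 1..6 at rows {list(bad[:5])}")
    ok_rt = trials["rt_ms"].isna() | (trials["rt_ms"] > 0)
    if not ok_rt.all():
        raise ValueError(
            f"non-positive RTs at rows {list(trials.index[~ok_rt][:5])}")


def recognition_vs_chance(accuracies, direction: str = "positive"):
    """Directional one-sample BF of per-participant accuracies against 0.5.

    Accuracies are proportions in [0, 1]; the test is run on
    ``accuracy - 0.5``, the deviation from guessing on the two-alternative
    recognition task.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.size == 0:
        raise ValueError("no accuracies given")
    if np.any((acc < 0) | (acc > 1)):
        raise ValueError("accuracies must lie in [0, 1]")
    t, n = one_sample_t(acc - 0.5)
    return jzs_bf_one_sample(t, n, direction=direction)


def _arm_tables(trials: pd.DataFrame, arm: str):
    kept, _ = filter_trials(trials)

    eff_rep = latency_normalized_difference(condition_medians(kept, by_repetition=True))
    eff_all = latency_normalized_difference(condition_medians(kept, by_repetition=False))

    per_rep = []
    for rep, grp in eff_rep.groupby("repetition"):
        row = {"arm": arm, "repetition": int(rep)}
        row.update(_bf_row(grp["d"].to_numpy()))
        # ms-equivalent from the group mean of the pooled condition medians,
        # so the percent and ms rows are mutually consistent
        row["ms_equivalent"] = row["mean_d"] * float(grp["mean_median_rt"].mean())
        per_rep.append(row)
    per_rep = pd.DataFrame(per_rep)

    overall = {"arm": arm, "repetition": "all"}
    overall.update(_bf_row(eff_all["d"].to_numpy()))
    overall["ms_equivalent"] = overall["mean_d"] * float(eff_all["mean_median_rt"].mean())
    overall = pd.DataFrame([overall])

    # profile model comparison: d-profile and recognition-accuracy profile
    mc_rows = []
    d_profile = per_rep.sort_values("repetition")["mean_d"].to_numpy()
    recog_profile = (
        trials.groupby("repetition")["recognition_correct"]
        .mean().sort_index().to_numpy(dtype=float)
    )
    for outcome, y in (("target_detection", d_profile), ("recognition", recog_profile)):
        fits, _ = compare_families(y)
        tab = fits_table(fits)
        tab.insert(0, "outcome", outcome)
        tab.insert(0, "arm", arm)
        tab["rank"] = np.arange(1, len(tab) + 1)
        mc_rows.append(tab)
    model_comparison = pd.concat(mc_rows, ignore_index=True)

    acc = trials.groupby("participant_id")["recognition_correct"].mean().to_numpy(dtype=float)
    rec = recognition_vs_chance(acc)
    recognition = pd.DataFrame([{
        "arm": arm, "mean_accuracy": float(np.mean(acc)),
        "sd_accuracy": float(np.std(acc, ddof=1)),
        "t": rec.t, "bf_plus": rec.bf, "log_bf": rec.log_bf, "evidence": rec.evidence,
    }])

    loc = trials.groupby("participant_id")["localization_correct"].mean().to_numpy(dtype=float)
    localization = pd.DataFrame([{
        "arm": arm, "mean_accuracy": float(np.mean(loc)),
        "sd_accuracy": float(np.std(loc, ddof=1)),
        "timeout_rate": float(trials["timed_out"].fillna(False).mean()),
    }])

    norm = normality_check(eff_rep)
    norm.insert(0, "arm", arm)

    return per_rep, overall, model_comparison, recognition, localization, norm, eff_rep


def _between_arms(eff_by_arm: dict) -> pd.DataFrame:
    # the directional hypothesis is a *larger* effect under interocular
    # suppression, so that arm is always group a
    items = sorted(eff_by_arm.items(),
                   key=lambda kv: (kv[0] != "suppression", kv[0]))
    (arm_a, eff_a), (arm_b, eff_b) = items
    rows = []
    for rep in sorted(eff_a["repetition"].unique()):
        da = eff_a.loc[eff_a["repetition"] == rep, "d"].to_numpy()
        db = eff_b.loc[eff_b["repetition"] == rep, "d"].to_numpy()
        t = t_from_two_summaries(da.mean(), da.std(ddof=1), da.size,
                                 db.mean(), db.std(ddof=1), db.size)
        res = jzs_bf_two_sample(t, da.size, db.size, direction="positive")
        rows.append({"repetition": int(rep), "arm_a": arm_a, "arm_b": arm_b,
                     "mean_d_a": da.mean(), "mean_d_b": db.mean(), "t": res.t,
                     "bf_plus": res.bf, "bf_null": res.bf_null, "evidence": res.evidence})
    return pd.DataFrame(rows)


def run_analysis(trials: pd.DataFrame, config: dict | None = None) -> AnalysisReport:
    """Run the full analysis on a tidy trial table (one arm or two)."""
    config = config or {}
    validate_trials(trials)

    arms = sorted(trials["arm"].unique())
    parts = {arm: _arm_tables(trials[trials["arm"] == arm], arm) for arm in arms}

    between = None
    if len(arms) == 2:
        between = _between_arms({arm: parts[arm][6] for arm in arms})

    content = hashlib.sha256(
        pd.util.hash_pandas_object(trials.fillna(-1), index=False).values.tobytes()
    ).hexdigest()
    report = AnalysisReport(
        per_repetition=pd.concat([parts[a][0] for a in arms], ignore_index=True),
        overall=pd.concat([parts[a][1] for a in arms], ignore_index=True),
        between_arms=between,
        model_comparison=pd.concat([parts[a][2] for a in arms], ignore_index=True),
        recognition=pd.concat([parts[a][3] for a in arms], ignore_index=True),
        localization=pd.concat([parts[a][4] for a in arms], ignore_index=True),
        normality=pd.concat([parts[a][5] for a in arms], ignore_index=True),
        provenance={
            "input_hash": content,
            "seed": trials.attrs.get("seed"),
            "config": config,
            "version": __version__,
        },
    )
    return report
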