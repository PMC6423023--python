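"""Synthetic trial-level data with configurable repetition-dependent effects.

Response times are drawn from a log-normal distribution: RTs are right-skewed
and the pipeline's headline statistic is median-based, so a multiplicative
condition effect on the log-normal *median* makes the expected
latency-normalized difference at repetition ``r`` equal ``delta[r]`` exactly:
match trials get median multiplier ``(1 - delta/2)`` and mismatch trials
``(1 + delta/2)``, so ``(m_mis - m_match) / mean(m) = delta``.

Participants get a log-normal random baseline (between-subject variability in
overall RT), which the latency normalization downstream is designed to remove.
Localization errors are independent Bernoulli events; recognition correctness
follows a saturating accuracy curve ``acc(r) = a - b * exp(-c * (r - 1))``,
rising across repetitions of the same memorandum.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .design import TRIAL_COLUMNS, DesignError, DesignSpec, build_design


@dataclass(frozen=True)
class EffectProfile:
    """True data-generating parameters of a simulated experiment.

    Parameters
    ----------
    delta : tuple of 6 floats
        Fractional congruence effect per repetition (expected
        latency-normalized RT difference; positive = matching faster).
    base_rt_mean : float
        Typical (median) response time in ms of an average participant.
    base_rt_cv : float
        Trial-level coefficient of variation of the log-normal RT noise.
    subject_sd : float
        Between-subject SD of the log baseline RT.
    recog_params : (a, b, c)
        Recognition accuracy curve ``acc(r) = a - b * exp(-c * (r - 1))``.
    loc_error_rate : float
        Probability of an incorrect left/right localization response.
    """

    delta: tuple = (0.0,) * 6
    base_rt_mean: float = 1450.0
    base_rt_cv: float = 0.45
    subject_sd: float = 0.2
    recog_params: tuple = (0.90, 0.10, 0.5)
    loc_error_rate: float = 0.018

    def __post_init__(self):
        d = np.asarray(self.delta, dtype=float)
        if d.size != 6:
            raise ValueError("delta must have length 6 (one per repetition)")
        if np.any(np.abs(d) >= 0.5):
            raise ValueError("each |delta_r| must be < 0.5")
        if np.any(1.0 - d / 2.0 <= 0):
            raise ValueError("profile implies non-positive RT medians")
        if not 0.0 <= self.loc_error_rate <= 0.1:
            raise ValueError("loc_error_rate must lie in [0, 0.1]")
        if self.base_rt_mean <= 0 or self.base_rt_cv <= 0:
            raise ValueError("base_rt_mean and base_rt_cv must be positive")
        acc = self.accuracy(np.arange(1, 7))
        if np.any(acc < 0.5) or np.any(acc > 1.0):
            raise ValueError("recognition accuracy must stay within [0.5, 1]")

    def accuracy(self, repetition):
        """Expected recognition accuracy at repetition ``r`` (1-based)."""
        a, b, c = self.recog_params
        return a - b * np.exp(-c * (np.asarray(repetition, dtype=float) - 1.0))


def load_preset(name: str):
    """Load a shipped preset ('exp1', 'exp2', 'null') -> (DesignSpec, EffectProfile).

    The presets encode the two study arms: a dichoptic-suppression experiment
    with a U-shaped congruence-effect profile, and a monocular control with a
    smaller, monotonically decaying profile, plus a zero-effect null profile.
    """
    res = importlib.resources.files("cfsbias").joinpath(f"presets/{name}.yaml")
    try:
        cfg = yaml.safe_load(res.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}") from None
    return spec_from_dict(cfg.get("design", {})), profile_from_dict(cfg.get("profile", {}))


def spec_from_dict(d: dict) -> DesignSpec:
    d = dict(d)
    if "color_pairs" in d:
        d["color_pairs"] = tuple(tuple(p) for p in d["color_pairs"])
    if "onset_jitter" in d:
        d["onset_jitter"] = tuple(d["onset_jitter"])
    return DesignSpec(**d)


def profile_from_dict(d: dict) -> EffectProfile:
    d = dict(d)
    for key in ("delta", "recog_params"):
        if key in d:
            d[key] = tuple(d[key])
    return EffectProfile(**d)


def simulate_participant(
    spec: DesignSpec,
    profile: EffectProfile,
    rng: np.random.Generator,
    participant_id: int = 0,
) -> pd.DataFrame:
    """Simulate one participant: design skeleton + responses."""
    df = build_design(spec, rng=rng, participant_id=participant_id)
    n = len(df)
    rep = df["repetition"].to_numpy()
    delta = np.asarray(profile.delta, dtype=float)[rep - 1]
    mult = np.where(df["congruence"].to_numpy() == "match", 1.0 - delta / 2.0, 1.0 + delta / 2.0)

    baseline = profile.base_rt_mean * np.exp(profile.subject_sd * rng.standard_normal())
    sigma = np.sqrt(np.log1p(profile.base_rt_cv**2))
    rt = baseline * mult * np.exp(sigma * rng.standard_normal(n))

    timed_out = rt > spec.max_rt
    df["rt_ms"] = np.where(timed_out, np.nan, rt)
    df["timed_out"] = timed_out
    df["localization_correct"] = rng.random(n) >= profile.loc_error_rate
    df["recognition_correct"] = rng.random(n) < profile.accuracy(rep)
    return df


def simulate_experiment(spec: DesignSpec, profile: EffectProfile) -> pd.DataFrame:
    """Simulate a full experiment (all participants) as one tidy trial table.

    Deterministic given ``spec.seed``; each participant consumes an
    independent child stream so the table is stable under changes of
    ``n_participants`` for the shared prefix of participants.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_participants)
    frames = [
        simulate_participant(spec, profile, np.random.default_rng(s), participant_id=p)
        for p, s in enumerate(streams)
    ]
    out = pd.concat(frames, ignore_index=True)
    out.attrs["seed"] = spec.seed
    return out


def write_trials(df: pd.DataFrame, path, seed=None) -> None:
    """Write a tidy trial CSV (UTF-8, header, missing RT as empty field).

    The generating seed is embedded as a leading ``# seed=`` comment line.
    """
    seed = df.attrs.get("seed") if seed is None else seed
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, index=False)


def read_trials(path) -> pd.DataFrame:
    """Read a tidy trial CSV written by :func:`write_trials`."""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        seed = None
        if first.startswith("# seed="):
            seed = int(first.split("=", 1)[1])
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial CSV missing columns: {sorted(missing)}")
    for col in ("localization_correct", "recognition_correct", "timed_out"):
        df[col] = df[col].astype("boolean")
    if seed is not None:
        df.attrs["seed"] = seed
    return df[TRIAL_COLUMNS]
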