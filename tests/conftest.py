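"""Shared fixtures and the independent brute-force Bayes-factor oracle."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from cfsbias.simulate import load_preset, simulate_experiment


def brute_force_jzs_bf(t, df, n_eff, r=0.707, direction="two_sided",
                       nodes=1_000_000):
    """Independent fixed-grid trapezoid JZS Bayes factor.

    Marginalizes the noncentral-t likelihood over the (half-)Cauchy prior on
    a uniform grid of effect sizes on [-50r, 50r] (or the relevant half-line)
    using scipy's density directly; deliberately shares no code path with the
    package's adaptive tan-transformed Gauss-Legendre implementation.
    """
    if direction == "two_sided":
        d = np.linspace(-50 * r, 50 * r, nodes)
        w = stats.cauchy.pdf(d, 0, r)
    elif direction == "positive":
        d = np.linspace(0.0, 50 * r, nodes)
        w = 2 * stats.cauchy.pdf(d, 0, r)
    elif direction == "negative":
        d = np.linspace(-50 * r, 0.0, nodes)
        w = 2 * stats.cauchy.pdf(d, 0, r)
    else:
        raise ValueError(direction)
    num = np.trapezoid(stats.nct.pdf(t, df, d * np.sqrt(n_eff)) * w, d)
    return num / stats.t.pdf(t, df)


@pytest.fixture(scope="session")
def bf_oracle():
    return brute_force_jzs_bf


@pytest.fixture(scope="session")
def exp1_preset():
    return load_preset("exp1")


@pytest.fixture(scope="session")
def exp2_preset():
    return load_preset("exp2")


@pytest.fixture(scope="session")
def null_preset():
    return load_preset("null")


@pytest.fixture(scope="session")
def exp1_trials(exp1_preset):
    """One simulated suppression-arm experiment (36 participants)."""
    spec, profile = exp1_preset
    return simulate_experiment(dataclasses.replace(spec, seed=20240117), profile)


@pytest.fixture(scope="session")
def large_exp1_trials(exp1_preset):
    """A 300-participant suppression-arm experiment for large-sample checks."""
    spec, profile = exp1_preset
    spec = dataclasses.replace(spec, n_participants=300, seed=424242)
    return simulate_experiment(spec, profile)
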