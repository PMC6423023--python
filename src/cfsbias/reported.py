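"""Published summary statistics of the two original experiments.

These are inputs, not outputs: the printed group means, SDs and AIC tables of
the original repeated-memorization b-CFS study (dichoptic-suppression
experiment and monocular control) against which the pipeline's recomputed
statistics are benchmarked.  Effects are latency-normalized RT differences in
percent; accuracies in percent; n = 36 participants per experiment.
"""

N_PARTICIPANTS = 36

#: AIC goodness-of-fit table: experiment/outcome -> family -> AIC.
#: "target_detection" is the latency-normalized RT-difference profile,
#: "recognition" the memory-task accuracy profile.
AIC_TABLE = {
    "exp1": {
        "target_detection": {"linear": 34.0, "exponential": 32.0,
                             "quadratic": 20.6, "cubic": 22.4},
        "recognition": {"linear": 30.8, "exponential": 14.8,
                        "quadratic": 22.6, "cubic": 19.5},
    },
    "exp2": {
        "target_detection": {"linear": 19.7, "exponential": 11.6,
                             "quadratic": 14.2, "cubic": 15.6},
        "recognition": {"linear": 36.1, "exponential": 23.5,
                        "quadratic": 25.9, "cubic": 26.4},
    },
}

#: Normalized congruence effects (percent faster on matching trials):
#: (mean, sd) where printed; per-repetition ms differences where only those
#: were printed.
EFFECT_SUMMARIES = {
    "exp1": {
        "overall": {"mean": 4.2, "sd": 7.7, "ms": 61.0},
        "rep1": {"mean": 7.9, "sd": 18.5, "ms": 128.0},
        "rep6": {"mean": 7.1, "sd": 15.0, "ms": 94.0},
    },
    "exp2": {
        "overall": {"mean": 1.0, "sd": 2.2, "ms": 11.0},
        "rep1": {"mean": 3.4, "sd": 5.8, "ms": 36.0},
        "rep6": {"mean": 0.3, "sd": 7.0, "ms": 6.0},
    },
}

#: Reported directional Bayes factors (BF_+0 unless noted).
REPORTED_BF = {
    "exp1_overall": 32.3,
    "exp1_rep1": 6.2,
    "exp1_rep6": 10.8,
    "exp1_rep4_bf0": 4.0,          # BF_0+ (evidence for the null)
    "exp2_overall": 5.8,
    "exp2_rep1": 51.8,
    "between_rep6": 6.1,           # independent-samples, rep-6 effect
}

#: Recognition-task accuracy (percent) and localization accuracy (percent).
RECOGNITION = {"exp1": {"mean": 85.8, "sd": 5.5}, "exp2": {"mean": 82.4, "sd": 6.7}}
LOCALIZATION = {"exp1": {"mean": 98.2, "sd": 2.7}, "exp2": {"mean": 99.3, "sd": 1.0}}

#: Reported rounded relative likelihoods: (experiment, outcome, model_a, model_b) -> RL.
REPORTED_RL = {
    ("exp1", "target_detection", "quadratic", "exponential"): 299,
    ("exp1", "target_detection", "quadratic", "linear"): 812,
    ("exp1", "recognition", "exponential", "quadratic"): 49,
    ("exp1", "recognition", "exponential", "cubic"): 10,
    ("exp2", "target_detection", "exponential", "cubic"): 7,
    ("exp2", "target_detection", "exponential", "quadratic"): 4,
}
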