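# Methods

## The experimental structure being modeled

Each participant completes 192 trials organized as 32 sequences of six
consecutive trials ("repetitions") in which the same color is memorized. On
every trial a target from either the memorized (match) or the discarded
(mismatch) color category must be localized left/right as fast as possible;
under interocular suppression (the dichoptic arm) the time to localize the
target indexes the time the target needs to reach awareness. The factors of
interest are Congruence (match/mismatch) and Repetition (1–6); color
category (two fixed pairs: red↔blue, green↔purple), retro-cue and target
hemifield are counterbalanced factors of non-interest.

The design builder enforces, per participant: exactly `n_sequences/2` trials
in every Congruence × Repetition cell (16 at defaults); each category cued
on `n_sequences/4` sequences (8); cued/discarded categories constant within
a sequence and paired; never the same cued category on consecutive
sequences; 3 match / 3 mismatch trials per sequence with match positions
drawn as random pattern/complement pairs so each repetition position is
matched in exactly half the sequences; retro-cue and hemifield balanced
within each cell. Category order is drawn by a greedy sampler with a
majority-forcing rule and restarts, which always terminates for balanced
counts. Exact *block*-level balance is arithmetically impossible (16-trial
blocks cannot hold 12 cells equally), so balance is enforced at experiment
level only; repetition counts per 16-trial block are within ±1 by
construction, congruence counts per block are left random. The response
clock starts at target-ramp onset, so the 300–600 ms onset jitter never
enters `rt_ms`.

## Synthetic data generator

RTs are log-normal: right-skewed, strictly positive, and closed under the
multiplicative condition effect. At repetition *r*, match trials get median
`B_i·(1 − δ_r/2)` and mismatch trials `B_i·(1 + δ_r/2)`, where `B_i` is a
log-normal subject baseline; the expected latency-normalized difference is
then exactly `δ_r`, making `δ` the directly interpretable (and recoverable)
effect parameter. RTs above 5000 ms are censored as timeouts (<2% under the
default presets). Localization errors are independent Bernoulli events;
recognition correctness is Bernoulli with saturating per-repetition
probability `acc(r) = a − b·e^{−c(r−1)}`.

Preset parameters encode the two study arms and were fixed analytically from
the reported group statistics, before any testing, as the generator's
defining conditions:

- `exp1` (suppression): δ = (0.079, 0.019, 0.028, 0.001, 0.052, 0.071),
  solved from the reported per-repetition %-effects (reps 2–5 from the
  reported ms effects divided by the mean median RT); baseline 1452 ms from
  the reported 61 ms ⇔ 4.2% pairing; trial-level CV 0.45, which under the
  median-of-16-trials sampling theory (SD of log-median ≈
  √(π/2)·σ/√n_cell) reproduces the reported per-repetition SD(d) ≈ 18.5%
  and pooled SD ≈ 7.7%; recognition curve (0.90, 0.10, 0.5) matching the
  reported 85.8% mean accuracy; localization error rate 0.018.
- `exp2` (monocular control): δ = (0.034, 0.010, 0.013, 0.001, 0.002,
  0.003), baseline 1100 ms, CV 0.135 (reported SDs 5.8%/2.2%), recognition
  (0.87, 0.11, 0.5) (82.4%), localization error rate 0.007.
- `null`: δ ≡ 0 in the `exp1` noise regime, for calibration.

Between-subject SD of the log baseline is 0.2 — a typical RT-literature
value; it is not identifiable from the reported statistics because the
latency normalization removes it, which is also why tests of the pipeline
are insensitive to it.

What the generator does *not* emulate: between-subject heterogeneity in
recognition ability (accuracy varies across subjects only through binomial
sampling, so simulated recognition-vs-chance evidence is stronger than in
real data); sequential dependencies (fatigue, learning of hues);
condition-dependent timeout or error rates; and any trial-level correlation
between RT and recognition. Passing tests therefore certify the statistical
machinery and the design logic, not these aspects of real data.

## Preprocessing

Timeout and localization-error trials are excluded before RT analysis
(errors likely reflect guesses; accuracy is analyzed separately). Medians
use the midpoint convention for even counts. The overall ("all
repetitions") effect pools trials before taking medians rather than
averaging per-repetition effects. `d` is antisymmetric under condition swap
and invariant to common rescaling of both medians; both properties are
tested. Shapiro–Wilk tests per repetition flag normality violations at
α = 0.05; a constant sample is reported as degenerate rather than tested.

## Bayes factors

BF₁₀ = ∫ f_ν(t; δ√n_eff) dπ(δ) / f_ν(t; 0) with π = Cauchy(0, r = 0.707);
directional variants use the truncated-renormalized half-Cauchy, the
convention of standard Bayesian t-test software, which yields the testable
identity (BF₊₀ + BF₋₀)/2 = BF₁₀. One-sample/paired: ν = n − 1, n_eff = n;
independent samples: ν = n₁ + n₂ − 2, n_eff = n₁n₂/(n₁ + n₂).

The substitution δ = r·tan θ maps the heavy-tailed prior to the uniform
measure on (−π/2, π/2) — naive truncation of the Cauchy tail is the main
failure mode this avoids — and the bounded smooth integrand is evaluated by
Gauss–Legendre rules of doubling order (65 → 2049 nodes) until successive
orders agree to 1e−8 relative; failure to converge warns rather than fails.
Log-density evaluation with max-shifted exponentiation keeps results finite
at extreme evidence (the recognition-vs-chance t ≈ 39 gives log₁₀ BF ≈ 27).
The implementation agrees with an independent brute-force fixed-grid
trapezoid oracle to < 1e−5 relative error and with pingouin's closed-form
two-sided JZS BF to < 1e−8.

The labels follow the BF ≥ 3 / ≤ 1/3 substantial-evidence convention, with
boundaries counted as substantial. No multiple-comparison correction is
applied across repetitions (posterior odds are interpretable per test,
consecutive repetitions are positively dependent, and the profile-level
model comparison adjudicates the overall progression); this stance is fixed,
not configurable.

## Model comparison

Families: linear, quadratic, cubic (exact least squares) and exponential
`y = a + b·e^{−c(x−1)}` — decay-to-asymptote with offset, the natural
saturating form for both the effect profile and the accuracy profile. The
exponential fit solves (a, b) linearly on a rate grid
c ∈ {0.001, 0.005, 0.01, 0.02, 0.05, 0.1, …, 3} and polishes the best start
with bounded nonlinear least squares; the near-zero starts let the family
reach its linear (c → 0) limit, a tested nesting property. AIC uses the
Gaussian least-squares form n·ln(max(RSS, 1e−12)/n) + 2k, with the residual
variance counted in k (linear 3, exponential 4, quadratic 4, cubic 5). Only
AIC differences carry meaning, and relative likelihoods
e^{0.5·ΔAIC} depend on nothing else, so the additive convention is
immaterial for adjudication. Fits target the 6 group means (the group
profile is what the adjudication concerns); ties in ranking break by
smaller k, then fixed family order.

At realistic noise the cubic — which nests any smooth 6-point shape for a
2-unit penalty — is a frequent runner-up, so family "wins" are assessed as
Monte Carlo rates: the U-profile generator is adjudicated quadratic in a
clear majority of replicates, the decaying monocular profile makes the
exponential the modal winner at the study's own sample size (n = 36), and a
saturating accuracy curve with small perturbations (SD 0.001) is
adjudicated exponential in a majority.

## Optional stopping

The rule: after a minimum of 20 participants, stop when the directional BFs
for *both* monitored effects (repetitions 1 and 6) are individually
conclusive — above 6 or below 1/6, possibly in different directions
("mixed") — with a look after every participant (the design specifies no
schedule; the finest one is the conservative default). A safety cap
(default 100) bounds simulations and is not part of the original design; a
configuration whose replicates hit the cap more than half the time raises
rather than returning misleading rates. Under the null profile the
directional test drifts to the null boundary: evidence-for-null decisions
dominate and false "alternative" stops are rare; under δ₁ = δ₆ = 0.15 with
low noise (CV 0.15) most replicates stop at exactly 20.

## Problem sizes and numerical conventions

Monte Carlo scales used by the test suite, chosen as the package's standard
verification sizes: 200 replicates per experiment arm for parameter
recovery and family-win rates at n = 36; 150 null and 60 strong-effect
replicates for stopping-rule calibration; 300-participant single runs for
large-sample recovery checks; all seeded and reproducible. RSS guard 1e−12
in the AIC; BF quadrature tolerance 1e−8 (tested at 1e−5 against the
independent oracle); the rounding of printed summary statistics (one
decimal) bounds how exactly published Bayes factors can be reproduced from
them, and the corresponding checks propagate that rounding interval.

## Known limitations

- The trial CSV dialect is self-defined; mapping layers for external
  deposits are out of scope.
- Recognition and localization responses are independent of RT by
  construction.
- AIC magnitudes from group-mean fits (n = 6) are not comparable to
  published AIC magnitudes of unknown convention; only differences and the
  qualitative family ranking are.
- The exponential family is fit with a decay parameterization (c > 0);
  growing profiles are captured via negative b.
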