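# Methods

## The decision model

Choices and response times are modelled as a Wiener process with drift `v`
and unit diffusion coefficient, absorbed at boundaries `0` (low-reward
lever) and `a` (high-reward lever) from starting point `zr·a`. Observed
response time is decision time plus a non-decision component: `t0 + d/2`
for the upper response and `t0 − d/2` for the lower (the fast-dm sign
convention for the execution-time asymmetry `d`). Inter-trial variability
follows the classical extension — starting point uniform on
`zr ± szr/2`, drift normal with SD `sv`, non-decision time uniform on
`t0 ± st0/2`. Because the diffusion coefficient is a free scale, it is
fixed at 1 throughout; parameter values are only comparable across analyses
sharing that convention (tools fixing σ = 0.1 report values 10× smaller).

The first-passage density at the lower boundary is evaluated as

```
f(t) = (1/a²) · exp(−v·a·w − v²t/2) · f̃(t/a²; w),     w = zr
```

where `f̃` is computed from whichever of the small-time or large-time series
expansions needs fewer terms, with truncation counts chosen analytically
from the requested tolerance (1e−7 per evaluation); both representations
agree to 1e−6 on their overlap, which the tests assert. Normal drift
variability is integrated in closed form at the density level (the
drift-dependent factor has a Gaussian integral); uniform starting-point and
non-decision variability use 10-node Gauss–Legendre quadrature, and drift
variability at the CDF level uses 24-node Gauss–Hermite quadrature. The
defective CDF uses the term-by-term integral of the large-time series for
`t/a² ≥ 0.05`, Gauss–Legendre integration of the small-time density below
that, and returns 0 where the accumulated mass is provably below ~e⁻³⁰.

Trial simulation is exact (no path discretisation): per trial the
effective starting point and drift are drawn, the boundary from the
analytic absorption probability, and the decision time by inverting the
conditional first-passage CDF with vectorised bisection. An
Euler–Maruyama path simulator is retained purely as an independent oracle;
its boundary-overshoot bias of order √dt is why oracle comparisons use
dt = 1e−5 with Monte-Carlo tolerances wider than that bias.

## The task generator

`task_sim` reproduces the study design: baseline sessions of 100 trials
(50 high / 50 low reward tones) and probe sessions of 120 trials
(40 high / 40 midpoint / 40 low), in pseudorandom orders constrained to at
most 4 consecutive trials of one tone (the paper-style "pseudorandom" is
otherwise unspecified; 4 is our choice). Midpoint outcomes are reinforced
50/50 at random. Omissions are a mixture of an explicit per-tone
probability and natural censoring of responses slower than the 20 s window;
premature responses fire with a flat per-trial probability before tone
processing. Tone frequencies, sound levels and pellet counts are treated as
metadata: their behavioural consequences live entirely in the per-tone
diffusion parameters of a `SubjectSpec`.

Cohort presets draw each subject from a population model chosen to mimic a
well-trained rat with a mildly pessimistic baseline: boundary
`a ~ N(1.2, 0.1)`, starting point `zr ~ N(0.47, 0.03)`, reference-tone
drifts `±2.2 ± 0.25`, midpoint drift `N(−0.8, 0.25)` (evidence units/s),
non-decision time `N(0.30, 0.04)` s, 3 % omissions and 3 % prematures.
Inter-trial variability parameters default to zero in the generator — they
are not identifiable from ~40 responded trials per tone, and carrying them
would only blur the recovery and dissociation analyses; the simulator and
densities support them fully. The `v_shift(δ)` preset adds δ to the
midpoint drift only (rapid-antidepressant/psychostimulant signature); the
`zr_shift(δ)` preset shifts the starting point session-wide
(chronic-antidepressant signature). The headline effect sizes used in the
tests are δv = +0.6 and δzr = +0.06, the latter fixed a priori by a power
analysis against pilot estimator noise (paired Δzr SD ≈ 0.04 → ~98 % power
at n = 13, α = 0.05).

What the generator does *not* emulate: training/shaping stages, learning or
drift of parameters within a session, sequential dependencies, satiety, or
RT contaminants (fast guesses, lapses). Passing tests therefore demonstrate
internal consistency of the analysis chain under the stated generative
model, not robustness to every property of real operant data.

## Fitting

Parameters are estimated per probe session by Nelder–Mead minimisation
(5 seeded restarts by default; x-tolerance 1e−4, objective tolerance 1e−5;
box bounds enforced by a finite penalty an optimiser can descend out of)
of either

* the mean negative log-likelihood of choices and response times
  (**default**), or
* the maximum over tones of the Kolmogorov–Smirnov distance between
  empirical and predicted *combined* distributions, in which
  low-reward-lever RTs are negated onto one signed axis (the fast-dm
  construction).

Maximum likelihood is the default on evidence, not taste: a recovery study
on simulated 120-trial probe sessions showed the KS criterion carries a
visible small-sample bias (starting point pulled toward 0.5 by ~0.02, drift
overcompensating by ~15 % relative), while ML recovery is near-unbiased
(sign tests across 100 sessions indistinguishable from zero) at equal cost.
The KS objective remains first-class — implemented, tested against exact
model quantiles, and selectable via `FitSpec(objective="ks")` — because it
is what KS-based tools minimise and is useful for comparability.

By default drift `v` and boundary `a` vary by tone while `zr` and `t0` are
shared across tones within a session; `d`, `szr`, `sv`, `st0` are fixed at
0 (poorly identifiable at this trial count) but can be freed or shared via
`FitSpec`. Omissions and premature responses carry no valid choice RT and
are removed before fitting, with counts reported in the `FitResult`. Fits
with fewer than 20 responded trials in a fitted condition are refused
explicitly. Initial values are data-driven (non-decision time just below
the fastest response; drifts from the choice split through the drift-free
absorption relation).

## Behavioural metrics

CBI divides by lever responses only — omissions and prematures are excluded
from the denominator, so CBI is a pure choice-composition measure (the
source text's "proportion of responses made" is ambiguous; this reading
keeps CBI invariant to response rate). Change-from-baseline is
drug − baseline, so positive deltas always mean a more positive bias;
vehicle sessions enter repeated-measures analyses via vehicle-centred
scores (subject minus cohort vehicle mean, summing to zero). Latencies are
summarised by the median (robust to the long 20 s tail) with the mean also
emitted. The QC filter excludes a subject whose reference-tone accuracy
fails to stay strictly above 60 % in any session; exactly 60 % excludes.

## Statistics

The battery mirrors an SPSS-style workflow: two-sided tests at α = 0.05;
one-sample t-tests of change scores against zero; repeated-measures ANOVA
with one or two within factors; split-plot mixed ANOVA with a
between-subjects group factor. The ANOVA engine computes classical sums of
squares from cell means for complete tables (incomplete tables are rejected
rather than silently dropped) and was verified to machine precision against
pingouin (one-way and two-way repeated measures; mixed design, including
unbalanced groups) and against R's `aov` error-strata decomposition for the
three-factor split-plot. Sphericity epsilons come from the pooled
orthonormal-contrast covariance; the Huynh–Feldt correction is applied when
Mauchly's test rejects at α = 0.05 (`hf_policy="auto"`; "always"/"never"
available, and epsilon plus Mauchly statistics are recorded either way —
whether the original SPSS analyses gated the correction is not knowable
from the source). Mauchly's p uses the standard first-order chi-square
approximation. Post-hoc t-tests are paired or independent, the latter gated
by Levene's test onto the Welch form, with Bonferroni adjustment
`p → min(1, m·p)`. Chronic-style weekly scores average each subject's two
consecutive probe sessions.

## Problem sizes in the test suite

The acceptance-style tests run at sizes chosen for a single CPU: density
conservation on the full 3×3×3 (a, zr, v) grid with and without
variability at 1e−6; simulator-vs-analytic KS agreement at n = 100 000
(α = 0.01); parameter recovery over 100 simulated probe sessions (median
|Δzr| ≤ 0.05, |Δa|/a ≤ 15 %, |Δv|/|v| ≤ 25 %, sign-test unbiasedness at
α = 0.01); the drift/starting-point dissociation over 15 replicate cohorts
of n = 13 per shift type (≥ 80 % detection of the injected parameter,
≤ 25 % false positives on the other); and 500-replicate null calibrations
of each battery member (rejection within [0.03, 0.07]). Cohort-scale fits
use 2 restarts with slightly relaxed tolerances (x 1e−3, objective 1e−4),
which the recovery study shows costs no measurable accuracy.

## Known limitations

* No hierarchical/shrinkage estimation: subjects are fit independently.
* The KS objective's small-sample bias is documented, not corrected.
* No collapsing bounds, leakage, contaminant mixtures or across-session
  learning; the generator and model share the same family, so
  model-misspecification robustness is untested by design.
* Percent-positive ANOVA cells can be undefined when a subject makes no
  lever response to a tone; such subjects are dropped from that ANOVA (the
  delta t-tests are unaffected).
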