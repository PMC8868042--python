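# Methods

## Problem setting

A new binary screening test (the *index* test — here an LED
transillumination device for detecting breast abnormalities) is compared
against a *reference* test (screening mammography) on N paired readings.
Each breast is treated as an independent unit: 170 participants
contribute 340 breast-level events, and no intra-person correlation is
modelled. The reference is itself imperfect: its sensitivity α and
specificity β are below 1, so the naive cross-classification against the
reference misstates the index test's true operating characteristics.

## The 2×2 table and its reconstruction

The computational atom is the cross-classification

|            | reference + | reference − |
|------------|-------------|-------------|
| index +    | a           | b           |
| index −    | c           | d           |

Validation studies often print only rounded summaries (N, sensitivity,
specificity, prevalence at one decimal) and never the cells.
`reconstruct_from_summary` inverts this: it searches exhaustively over
the reference-positive margin n₁ ∈ [0, N] and, within each margin, over
all a and d whose implied percentages round (half-up) to the printed
values. The three constraints are separable given n₁, so the search is
O(N²) and takes well under a second at N = 340. All candidates are
returned, sorted by (a, b); the caller decides. For the study summaries
(N = 340, Se 86.3, Sp 68.9, prevalence 68.8, one decimal) exactly one
table survives: (a, b, c, d) = (202, 33, 32, 73). A degenerate margin
(n₁ = 0 or N) leaves the corresponding undefined proportion
unconstrained.

Rounding is half-up on the printed scale throughout the package,
centralized in `round_half_up` (Python's built-in `round` is banker's
rounding and would disagree on ties). This is the convention under which
73/106 prints as 68.9%.

## Unadjusted profile

With the reference treated as truth: Se = a/(a+c), Sp = d/(b+d),
PPV = a/(a+b), NPV = d/(c+d), validity (accuracy) = (a+d)/N, prevalence
= (a+c)/N, Youden J = Se+Sp−1, LR+ = Se/(1−Sp), LR− = (1−Se)/Sp.

Proportion intervals default to the Wald interval with the 1/(2n)
continuity correction, p ± (z√(p(1−p)/n) + 1/(2n)), clamped to [0, 1].
This construction reproduces, at printed precision, all six proportion
intervals the study reports for the unadjusted column; Wilson and
Clopper–Pearson are available behind a flag (via statsmodels) for users
who prefer them. Likelihood-ratio intervals use the standard log method,
e.g. Var(ln LR+) = 1/a − 1/(a+c) + 1/b − 1/(b+d). The Youden interval
sums the two Wald variances of Se and Sp without a continuity term; it
is documented as approximate. Cohen's kappa is reported as a point
estimate without an interval. Indicators with a zero denominator are
returned as explicit "undefined" markers, never fabricated.

## Imperfect-reference correction

If the reference's (α, β) are known and the two tests err independently
given true disease status, method-of-moments estimators de-bias the
index test's accuracy:

    S = [β(a+b) − b] / [(a+c) − (1−β)N]
    E = [α(c+d) − c] / [Nα − (a+c)]
    D = [(a+c) − (1−β)N] / (α + β − 1),   π̂ = D/N

Identifiability requires (a+c) > (1−β)N (observed positives exceed the
reference's expected false positives) and (a+c) < Nα, plus α + β > 1
(enforced at `ReferenceProfile` construction). Downstream indicators
follow by Bayes' rule from (S, E, π̂): PPV = Sπ̂/(Sπ̂+(1−E)(1−π̂)),
NPV = E(1−π̂)/(E(1−π̂)+(1−S)π̂), validity = Sπ̂+E(1−π̂), J = S+E−1,
LR+ = S/(1−E), LR− = (1−S)/E. With a perfect reference (α = β = 1)
every corrected quantity reduces exactly to its naive counterpart — a
property-tested invariant.

Finite samples or mis-specified (α, β) can push S or E outside [0, 1].
The default is flag-not-clamp: the raw value is returned with a warning
flag, because silent truncation hides mis-specification; an explicit
clamp mode is available.

The post-test probability converts the *observed* (uncorrected)
prevalence to odds and multiplies by the corrected LR+. The rationale:
the observed positivity rate is the empirical pre-test probability for
this population, while the corrected LR+ is the best estimate of the
index test's evidential strength. On the study table this gives
odds(0.688)·24.87 → 98.2%.

α and β are treated as fixed known constants, not estimates with
uncertainty; no closed-form interval is offered for the corrected
estimators (see "Not reproduced" below). A nonparametric bootstrap
(multinomial resampling of the N units, re-applying the correction,
percentile interval) is provided as a methodologically distinct option;
resamples where the correction is unidentifiable are dropped and
counted.

## Sample size

`buderer_sample_size` implements the precision-based formula:
n_diseased = ⌈z²·Se(1−Se)/d²⌉ for CI half-width d, analogously for the
non-diseased arm with Sp, scaled by the expected prevalence to an
overall recruitment figure. Degenerate precisions are allowed but warn.

## Synthetic cohorts

`simulate_cohort` draws breast-level units from a latent-class model:
true status ~ Bernoulli(π); given status, the index and reference
results have marginals (s, α) when diseased and (1−e, 1−β) positivity
when healthy, with a one-parameter agreement tilt

    P(both fire) = pq + δ·(min(p, q) − pq),   δ ∈ [0, 1].

δ = 0 is exact conditional independence (the correction's identifying
assumption); δ = 1 is maximal positive dependence given the margins.
This tilt preserves the marginals for every δ and keeps all four
conditional cells in [0, 1], which is checked in closed form at
parameter construction. One seeded `numpy` generator per cohort; no
global state; same seed ⇒ identical records.

The generator emulates paired binary readings with known truth. It does
not emulate continuous transillumination scores, reader variability,
within-woman correlation between breasts, or prevalence heterogeneity —
so passing calibration tests demonstrates the estimators' algebraic
consistency under the stated model, not robustness to those real-data
features. Default reference characteristics are the mammographic values
used throughout (α = 0.869, β = 0.889).

Calibration checks use N = 200,000 for the consistency test (corrected
estimates within ±0.01 of the generative (s, e) = (0.9, 0.95) at
π = 0.7, while naive estimates are biased by more than 0.01) and
N = 50,000–100,000 for cell-frequency and perfect-reference checks,
asserted within 3 Monte-Carlo standard errors. These sizes make the
Monte-Carlo error an order of magnitude smaller than the tolerances
while keeping the suite fast.

## Study fixtures

The source study printed only margins, so the packaged fixtures are
exact-margin reconstructions with synthetic joint structure, and say so:
findings flags are assigned maximally-overlapping from the start of a
fixed unit order (every breast dense under the mammogram is also dense
under the index device), and the survey's single missing response per
item is pinned to one synthetic non-respondent (the 170th participant,
yielding 169 respondents per item). Fixtures are pure functions —
regeneration is byte-identical.

Descriptive tallies always report the denominator they used: 340
breast-events for findings, per-question respondent counts (missing
excluded) for the survey. Adding a fully-missing record changes no
percentage.

## Not reproduced, by design

Four reported figures are surfaced in every report under
`not_reproduced` rather than silently skipped:

* **Kappa** — the source prints 0.54 in prose and 0.56 in its table; the
  reconstructed table yields 0.553, matching neither at two decimals.
  This package asserts its own hand-derived 0.553.
* **Pre-test probability 54.7** — matches no quantity derivable from the
  reconstructed table under standard definitions; the printed post-test
  98.2 follows from the observed prevalence 68.8, not from 54.7.
* **Adjusted-column CIs** — the original software's variance formula is
  undisclosed and its printed specificity interval exceeds 100%; the
  bootstrap option is offered instead.
* **Minimum sample size 296** — produced by an undisclosed formula under
  an incoherent "power 80% / alpha 95%" precision parameterization; the
  implemented formula makes no claim to reproduce it.

## Numerical notes and limitations

* All tie-breaking in reconstruction ordering is lexicographic in (a, b).
* Proportion CI bounds are clamped to [0, 1]; the Youden interval is not
  clamped (it is not a proportion).
* LR− is exactly 0 when S = 1; LR+ is an undefined marker when E = 1.
* The correction assumes conditional independence and known (α, β); the
  simulator can generate dependence (δ > 0) precisely so users can see
  the correction degrade, but no dependence-corrected estimator is
  provided.
* Units are breasts; clustered (per-person) inference is out of scope.
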