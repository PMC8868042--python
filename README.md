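# diagval

Diagnostic-test accuracy against an **imperfect reference standard**, for
epidemiologists and biostatisticians validating a new binary screening
test when the comparator itself misclassifies.

The motivating application is the validation of an LED transillumination
breast-screening device against mammography on 340 breast-level readings,
where the mammogram's own operating characteristics (sensitivity
α = 0.869, specificity β = 0.889) are known from the literature.

## What it computes

Given the paired 2×2 table

|          | reference + | reference − |
|----------|-------------|-------------|
| index +  | a           | b           |
| index −  | c           | d           |

the package provides:

* **Unadjusted profile** — Se = a/(a+c), Sp = d/(b+d), PPV, NPV,
  validity index, prevalence, Youden J, LR±, Cohen's kappa, with
  continuity-corrected Wald intervals for proportions and log-method
  intervals for likelihood ratios.
* **Imperfect-reference correction** — with known (α, β) and
  conditionally independent errors, the de-biased index-test estimators

      S = [β(a+b) − b] / [(a+c) − (1−β)N]
      E = [α(c+d) − c] / [Nα − (a+c)]

  plus the corrected prevalence π̂ = D/N with
  D = [(a+c) − (1−β)N]/(α+β−1), and all downstream indicators (PPV,
  NPV, validity, Youden, LR±, post-test probability) by Bayes' rule.
* **Table reconstruction** — exhaustive recovery of every integer 2×2
  table consistent with printed rounded summaries (N, Se%, Sp%,
  prevalence%), for re-analysing studies that never printed their cells.
* **Latent-class simulation** — per-breast cohorts with latent disease
  status, an imperfect reference and an index test, a one-parameter
  conditional-dependence tilt, and known truth, for end-to-end testing
  of every estimator.
* **Descriptive tallies** — device-wise findings and acceptability-survey
  percentages with explicit missing-value denominators.
* **Precision-based sample size** for sensitivity/specificity studies.

See `docs/methods.md` for the model, assumptions, and the handful of
reported figures the package documents as not reproducible.

## Worked example

```python
from diagval import (ReferenceProfile, SummaryConstraints,
                     reconstruct_from_summary, evaluate, render_text)

# Recover the study's table from its printed rounded summaries
(table,) = reconstruct_from_summary(
    SummaryConstraints(n=340, se_pct=86.3, sp_pct=68.9, prev_pct=68.8, decimals=1))
print(table)   # PairedTable(a=202, b=33, c=32, d=73)

doc = evaluate(table, ReferenceProfile(alpha=0.869, beta=0.889))
print(render_text(doc))
```

prints (abridged):

```
Parameter                 Unadjusted          95% CI    Adjusted
Sensitivity (%)                 86.3       81.7-90.9        89.6
Specificity (%)                 68.9       59.6-78.2        96.4
Validity index (%)              80.9       76.6-85.2        91.2
Predictive value + (%)          86.0       81.3-90.6        98.8
Predictive value - (%)          69.5       60.2-78.8        74.4
Prevalence (%)                  68.8       63.8-73.9        76.2
Youden index                     0.6         0.5-0.7         0.9
Likelihood ratio +               2.8         2.1-3.7        24.9
Likelihood ratio -              0.20       0.14-0.28        0.11
Post-test probability                                       98.2
Kappa                           0.55
```

Reading: against the mammogram's readings the device looks 86.3%
sensitive and only 68.9% specific, but once the mammogram's own error
rates are corrected for, the device's estimated true sensitivity is
89.6% and specificity 96.4%; a positive device result raises the
disease probability from the observed 68.8% positivity rate to 98.2%.

The same pipeline is available from a shell:

```sh
diagval evaluate --table 202,33,32,73 --alpha 0.869 --beta 0.889
diagval reconstruct --n 340 --se 86.3 --sp 68.9 --prev 68.8
diagval simulate --n-units 10000 --prevalence 0.7 --sensitivity 0.9 \
    --specificity 0.95 --seed 1 --output cohort.csv --manifest manifest.json
diagval fixtures --outdir fixtures/ && diagval tally \
    --findings fixtures/findings.csv --survey fixtures/survey.csv
```

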