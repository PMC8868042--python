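"""Imperfect-reference correction for index-test accuracy.

When the reference standard itself misclassifies — it has sensitivity
alpha < 1 and/or specificity beta < 1 — the naive estimates of the index
test's Se and Sp are biased.  If (alpha, beta) are known and the two
tests' errors are conditionally independent given true disease status,
method-of-moments estimators remove that bias:

    S = [beta (a+b) - b] / [(a+c) - (1-beta) N]        (index sensitivity)
    E = [alpha (c+d) - c] / [N alpha - (a+c)]          (index specificity)
    D = [(a+c) - (1-beta) N] / (alpha + beta - 1)      (true diseased count)

The denominators require the observed reference-positive count to exceed
the reference's expected false positives and fall short of its expected
(true + false) positives; otherwise the correction is not identifiable.
With a perfect reference (alpha = beta = 1) every corrected quantity
reduces exactly to its naive counterpart.

With finite samples or mis-specified (alpha, beta), S or E can land
outside [0, 1]; such values are returned raw with a flag — silent
clamping would hide the mis-specification — unless clamping is
explicitly requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import NotIdentifiableError
from .tables import PairedTable, ReferenceProfile


def adjusted_sensitivity(table: PairedTable, ref: ReferenceProfile) -> float:
    """Corrected index-test sensitivity S; may fall outside [0, 1]."""
    denominator = table.ref_pos - (1.0 - ref.beta) * table.n
    if denominator <= 0:
        raise NotIdentifiableError(
            "not identifiable: reference positives <= expected false positives"
        )
    return (ref.beta * table.index_pos - table.b) / denominator


def adjusted_specificity(table: PairedTable, ref: ReferenceProfile) -> float:
    """Corrected index-test specificity E; may fall outside [0, 1]."""
    denominator = table.n * ref.alpha - table.ref_pos
    if denominator <= 0:
        raise NotIdentifiableError(
            "not identifiable: reference positives >= expected true+false positives"
        )
    return (ref.alpha * table.index_neg - table.c) / denominator


def estimated_disease_count(table: PairedTable, ref: ReferenceProfile) -> float:
    """Estimated number of truly diseased units, D (real-valued)."""
    # ReferenceProfile guarantees alpha + beta > 1.
    return (table.ref_pos - (1.0 - ref.beta) * table.n) / (ref.alpha + ref.beta - 1.0)


def post_test_probability(pre_test: float, lr: float) -> float:
    """Bayes update of a disease probability through a likelihood ratio."""
    if not 0.0 < pre_test < 1.0:
        raise ValueError(f"pre-test probability must lie strictly in (0, 1), got {pre_test}")
    if not lr > 0.0 or math.isinf(lr):
        raise ValueError(f"likelihood ratio must be finite and positive, got {lr}")
    odds = pre_test / (1.0 - pre_test) * lr
    return odds / (1.0 + odds)


@dataclass(frozen=True)
class AdjustedAccuracyReport:
    """Every corrected indicator for one table and reference profile.

    ``flags`` lists human-readable warnings (out-of-range estimates,
    undefined ratios); ``clamped`` records whether out-of-range S/E/
    prevalence were truncated into their valid ranges before the
    downstream indicators were computed.
    """

    sensitivity: float
    specificity: float
    disease_count: float
    prevalence: float
    ppv: float
    npv: float
    validity_index: float
    youden: float
    lr_pos: float
    lr_neg: float
    post_test_probability: float
    flags: tuple[str, ...] = ()
    clamped: bool = False

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "disease_count": self.disease_count,
            "prevalence": self.prevalence,
            "ppv": self.ppv,
            "npv": self.npv,
            "validity_index": self.validity_index,
            "youden": self.youden,
            "lr_pos": self.lr_pos,
            "lr_neg": self.lr_neg,
            "post_test_probability": self.post_test_probability,
            "flags": list(self.flags),
            "clamped": self.clamped,
        }


def adjusted_report(
    table: PairedTable, ref: ReferenceProfile, clamp: bool = False
) -> AdjustedAccuracyReport:
    """Compute the full corrected indicator set.

    Downstream indicators follow from (S, E) and the corrected prevalence
    pi = D/N by Bayes' rule:

        PPV = S pi / [S pi + (1-E)(1-pi)]
        NPV = E (1-pi) / [E (1-pi) + (1-S) pi]
        validity = S pi + E (1-pi)
        LR+ = S/(1-E),  LR- = (1-S)/E

    The post-test probability pairs the *observed* (uncorrected)
    prevalence, converted to odds, with the corrected LR+: the question
    it answers is "given the positivity rate actually seen in this
    population, what does a positive index result imply once the index
    test's true operating characteristics are used?".
    """
    flags: list[str] = []
    s = adjusted_sensitivity(table, ref)
    e = adjusted_specificity(table, ref)
    d_count = estimated_disease_count(table, ref)
    prev = d_count / table.n

    for name, value in (("sensitivity", s), ("specificity", e), ("prevalence", prev)):
        if not 0.0 <= value <= 1.0:
            flags.append(f"adjusted {name} {value:.4f} outside [0, 1]")
    if clamp:
        s = min(max(s, 0.0), 1.0)
        e = min(max(e, 0.0), 1.0)
        prev = min(max(prev, 0.0), 1.0)
        d_count = prev * table.n

    ppv_num, ppv_den = s * prev, s * prev + (1.0 - e) * (1.0 - prev)
    npv_num, npv_den = e * (1.0 - prev), e * (1.0 - prev) + (1.0 - s) * prev
    ppv = ppv_num / ppv_den if ppv_den != 0.0 else float("nan")
    npv = npv_num / npv_den if npv_den != 0.0 else float("nan")
    validity = s * prev + e * (1.0 - prev)
    youden = s + e - 1.0

    if e == 1.0:
        lr_pos = float("nan")
        flags.append("LR+ undefined: adjusted specificity is 1")
    else:
        lr_pos = s / (1.0 - e)
    lr_neg = 0.0 if s == 1.0 else (1.0 - s) / e

    pre_test = table.ref_pos / table.n
    if math.isnan(lr_pos) or lr_pos <= 0.0 or not 0.0 < pre_test < 1.0:
        post = float("nan")
        flags.append("post-test probability undefined")
    else:
        post = post_test_probability(pre_test, lr_pos)

    return AdjustedAccuracyReport(
        sensitivity=s,
        specificity=e,
        disease_count=d_count,
        prevalence=prev,
        ppv=ppv,
        npv=npv,
        validity_index=validity,
        youden=youden,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        post_test_probability=post,
        flags=tuple(flags),
        clamped=clamp,
    )


def bootstrap_adjusted_ci(
    table: PairedTable,
    ref: ReferenceProfile,
    level: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Nonparametric bootstrap percentile CIs for the corrected S and E.

    Resamples N units from the observed cell proportions (multinomial),
    re-applies the correction to each resample, and takes percentile
    intervals.  This is methodologically distinct from any closed-form
    variance construction for the corrected estimators and is labelled as
    such in the result.  Resamples where the correction is not
    identifiable are dropped and counted.
    """
    rng = np.random.default_rng(seed)
    cells = np.array([table.a, table.b, table.c, table.d], dtype=float)
    draws = rng.multinomial(table.n, cells / table.n, size=n_boot)
    s_values: list[float] = []
    e_values: list[float] = []
    dropped = 0
    for a, b, c, d in draws:
        if a + b + c + d == 0:
            dropped += 1
            continue
        resample = PairedTable(int(a), int(b), int(c), int(d))
        try:
            s_values.append(adjusted_sensitivity(resample, ref))
            e_values.append(adjusted_specificity(resample, ref))
        except NotIdentifiableError:
            dropped += 1
    lo, hi = 100.0 * (0.5 - level / 2.0), 100.0 * (0.5 + level / 2.0)
    return {
        "method": "bootstrap_percentile",
        "level": level,
        "n_boot": n_boot,
        "n_dropped_not_identifiable": dropped,
        "sensitivity": (
            float(np.percentile(s_values, lo)),
            float(np.percentile(s_values, hi)),
        ),
        "specificity": (
            float(np.percentile(e_values, lo)),
            float(np.percentile(e_values, hi)),
        ),
    }
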