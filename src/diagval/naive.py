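"""Unadjusted (reference-as-truth) accuracy profile of the index test.

Treating the reference test's result as disease status, a 2x2 table yields
the classical screening indicators:

    Se = a/(a+c)        Sp = d/(b+d)
    PPV = a/(a+b)       NPV = d/(c+d)
    validity (accuracy) = (a+d)/N
    prevalence = (a+c)/N
    Youden J = Se + Sp - 1
    LR+ = Se/(1-Sp)     LR- = (1-Se)/Sp

Proportion confidence intervals default to the Wald interval with a
1/(2n) continuity correction — the construction that matches how such
validation studies conventionally print their intervals.  Wilson and
Clopper-Pearson are available behind the ``method`` flag (delegated to
statsmodels).  Likelihood-ratio intervals use the standard log method.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

from scipy.stats import norm

from .errors import DegenerateIntervalError, UndefinedStatisticError
from .tables import PairedTable

_UNDEFINED = float("nan")


@dataclass(frozen=True)
class EstimateWithCI:
    """A point estimate with a two-sided confidence interval.

    ``method`` is one of wald_cc, wald, wilson, exact, log_ratio, none;
    ``none`` marks an undefined estimate (NaN point, no interval).
    """

    point: float
    lower: float
    upper: float
    level: float
    method: str

    @property
    def defined(self) -> bool:
        return self.method != "none" and not math.isnan(self.point)

    def to_dict(self) -> dict:
        return {
            "point": self.point,
            "lower": self.lower,
            "upper": self.upper,
            "level": self.level,
            "method": self.method,
        }

    @classmethod
    def undefined(cls, level: float) -> "EstimateWithCI":
        return cls(_UNDEFINED, _UNDEFINED, _UNDEFINED, level, "none")


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    return float(norm.ppf(0.5 + level / 2.0))


def proportion_ci(
    successes: int,
    trials: int,
    level: float = 0.95,
    continuity_correction: bool = True,
    method: str = "wald",
) -> EstimateWithCI:
    """Confidence interval for a binomial proportion.

    Default is the Wald interval widened by the 1/(2n) continuity term,
    with bounds clamped to [0, 1].  ``method`` may instead be "wilson" or
    "exact" (Clopper-Pearson); those ignore ``continuity_correction``.
    """
    if trials <= 0:
        raise UndefinedStatisticError("undefined proportion: zero trials")
    if not 0 <= successes <= trials:
        raise ValueError(f"successes must lie in [0, {trials}], got {successes}")
    point = successes / trials
    if method == "wald":
        half = _z(level) * math.sqrt(point * (1.0 - point) / trials)
        if continuity_correction:
            half += 1.0 / (2.0 * trials)
        lower, upper = point - half, point + half
        label = "wald_cc" if continuity_correction else "wald"
    elif method in ("wilson", "exact"):
        from statsmodels.stats.proportion import proportion_confint

        sm_method = {"wilson": "wilson", "exact": "beta"}[method]
        lower, upper = proportion_confint(successes, trials, 1.0 - level, sm_method)
        label = method
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return EstimateWithCI(point, max(0.0, lower), min(1.0, upper), level, label)


def log_ratio_ci(
    table: PairedTable, which: str = "positive", level: float = 0.95
) -> EstimateWithCI:
    """Log-method confidence interval for a likelihood ratio.

    LR+ = [a/(a+c)] / [b/(b+d)], with
    Var(ln LR+) = 1/a - 1/(a+c) + 1/b - 1/(b+d); LR- uses cells c and d
    analogously.  Requires both defining cells to be positive and the LR
    to be finite and positive.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n1, n2 = table.ref_pos, table.ref_neg
    if n1 == 0 or n2 == 0:
        raise DegenerateIntervalError("degenerate LR interval: empty margin")
    if which == "positive":
        num_cell, den_cell = a, b
    elif which == "negative":
        num_cell, den_cell = c, d
    else:
        raise ValueError(f"which must be 'positive' or 'negative', got {which!r}")
    if num_cell == 0 or den_cell == 0:
        raise DegenerateIntervalError(
            "degenerate LR interval: zero cell makes the LR or its variance degenerate"
        )
    point = (num_cell / n1) / (den_cell / n2)
    variance = 1.0 / num_cell - 1.0 / n1 + 1.0 / den_cell - 1.0 / n2
    half = _z(level) * math.sqrt(variance)
    return EstimateWithCI(
        point,
        point * math.exp(-half),
        point * math.exp(half),
        level,
        "log_ratio",
    )


@dataclass(frozen=True)
class AccuracyProfile:
    """The full unadjusted indicator set for one table."""

    sensitivity: EstimateWithCI
    specificity: EstimateWithCI
    ppv: EstimateWithCI
    npv: EstimateWithCI
    validity_index: EstimateWithCI
    prevalence: EstimateWithCI
    youden: EstimateWithCI
    lr_pos: EstimateWithCI
    lr_neg: EstimateWithCI
    n: int

    def to_dict(self) -> dict:
        payload = {
            name: getattr(self, name).to_dict()
            for name in (
                "sensitivity",
                "specificity",
                "ppv",
                "npv",
                "validity_index",
                "prevalence",
                "youden",
                "lr_pos",
                "lr_neg",
            )
        }
        payload["n"] = self.n
        return payload


def naive_profile(
    table: PairedTable,
    level: float = 0.95,
    continuity_correction: bool = True,
) -> AccuracyProfile:
    """Compute every unadjusted indicator with its interval.

    Any indicator whose denominator is zero is returned as an undefined
    marker rather than fabricated.
    """

    def prop(successes: int, trials: int) -> EstimateWithCI:
        if trials == 0:
            return EstimateWithCI.undefined(level)
        return proportion_ci(successes, trials, level, continuity_correction)

    se = prop(table.a, table.ref_pos)
    sp = prop(table.d, table.ref_neg)

    if se.defined and sp.defined:
        j_point = se.point + sp.point - 1.0
        # Independent binomial variances of Se and Sp on the Wald scale;
        # no continuity term (the interval is already approximate).
        variance = se.point * (1.0 - se.point) / table.ref_pos + sp.point * (
            1.0 - sp.point
        ) / table.ref_neg
        half = _z(level) * math.sqrt(variance)
        youden = EstimateWithCI(j_point, j_point - half, j_point + half, level, "wald")
    else:
        youden = EstimateWithCI.undefined(level)

    def lr(which: str) -> EstimateWithCI:
        try:
            return log_ratio_ci(table, which, level)
        except DegenerateIntervalError:
            return EstimateWithCI.undefined(level)

    return AccuracyProfile(
        sensitivity=se,
        specificity=sp,
        ppv=prop(table.a, table.index_pos),
        npv=prop(table.d, table.index_neg),
        validity_index=prop(table.a + table.d, table.n),
        prevalence=prop(table.ref_pos, table.n),
        youden=youden,
        lr_pos=lr("positive"),
        lr_neg=lr("negative"),
        n=table.n,
    )


def cohen_kappa(table: PairedTable) -> float:
    """Chance-corrected agreement between the two tests.

    kappa = (po - pe) / (1 - pe) with po = (a+d)/N and
    pe = [(a+b)(a+c) + (c+d)(b+d)] / N^2.  Perfect observed agreement
    returns exactly 1; pe = 1 with po < 1 is undefined.
    """
    n = table.n
    po = (table.a + table.d) / n
    pe = (table.index_pos * table.ref_pos + table.index_neg * table.ref_neg) / (n * n)
    if po == 1.0:
        return 1.0
    if pe == 1.0:
        raise UndefinedStatisticError("undefined kappa: chance agreement is 1")
    return (po - pe) / (1.0 - pe)


@dataclass(frozen=True)
class SampleSizeSpec:
    """Inputs to precision-based sample-size estimation for a diagnostic study."""

    expected_sensitivity: float
    expected_specificity: float
    precision: float
    confidence: float = 0.95
    expected_prevalence: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "expected_sensitivity",
            "expected_specificity",
            "precision",
            "confidence",
            "expected_prevalence",
        ):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {value}")


@dataclass(frozen=True)
class SampleSizeResult:
    n_diseased: int
    n_nondiseased: int
    n_overall: int


def buderer_sample_size(spec: SampleSizeSpec) -> SampleSizeResult:
    """Units needed so the Wald CI half-width on Se and Sp is at most ``precision``.

    diseased = ceil(z^2 Se(1-Se) / precision^2); non-diseased analogously
    with Sp; overall recruitment is the larger of scaling each arm up by
    the expected prevalence (or its complement).
    """
    z = _z(spec.confidence)
    if spec.precision >= min(spec.expected_sensitivity, 1.0 - spec.expected_sensitivity):
        warnings.warn(
            "precision is as large as the expected error rate; "
            "the resulting sample size is vacuous",
            stacklevel=2,
        )
    se, sp = spec.expected_sensitivity, spec.expected_specificity
    n_dis = max(1, math.ceil(z * z * se * (1.0 - se) / spec.precision**2))
    n_non = max(1, math.ceil(z * z * sp * (1.0 - sp) / spec.precision**2))
    overall = max(
        math.ceil(n_dis / spec.expected_prevalence),
        math.ceil(n_non / (1.0 - spec.expected_prevalence)),
    )
    return SampleSizeResult(n_dis, n_non, overall)
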