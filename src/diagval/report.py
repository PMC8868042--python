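"""Report assembly: unadjusted + corrected columns in one document.

The text renderer mirrors the two-column layout such validation studies
print: one row per indicator, unadjusted value and 95% CI beside the
imperfect-reference-corrected value.  Mixed printed precisions follow
the field's convention: percentages and LR+ to one decimal, Youden to
one decimal, LR- and kappa to two.
"""

from __future__ import annotations

import json
import math
from typing import Optional

from .adjusted import AdjustedAccuracyReport, adjusted_report
from .naive import AccuracyProfile, cohen_kappa, naive_profile
from .rounding import round_half_up
from .tables import PairedTable, ReferenceProfile


def known_discrepancies() -> dict:
    """Source-study figures this package deliberately does not reproduce.

    Each entry records the reported figure, what this package computes
    (if anything), and why the gap exists.  They are surfaced in every
    report rather than silently skipped.
    """
    return {
        "kappa": {
            "reported": [0.54, 0.56],
            "computed": 0.553,
            "note": (
                "the source report prints two different kappa values (0.54 in "
                "prose, 0.56 in its results table); the reconstructed table "
                "yields 0.553, matching neither at two decimals"
            ),
        },
        "pre_test_probability": {
            "reported": 54.7,
            "computed": None,
            "note": (
                "the printed pre-test probability matches no quantity derivable "
                "from the reconstructed table under standard definitions; the "
                "printed post-test probability follows from the observed "
                "prevalence (68.8%) as the pre-test value, not from 54.7"
            ),
        },
        "adjusted_cis": {
            "reported": "e.g. adjusted specificity CI 81.3-115.9",
            "computed": None,
            "note": (
                "the source software's variance formula for the corrected "
                "estimators is undisclosed and its printed intervals exceed "
                "100%; a nonparametric bootstrap is offered instead as a "
                "methodologically distinct alternative"
            ),
        },
        "sample_size_296": {
            "reported": 296,
            "computed": None,
            "note": (
                "the reported minimum sample size of 296 came from an "
                "undisclosed formula under an incoherent 'power 80% / alpha "
                "95%' parameterization; the precision-based formula "
                "implemented here is not claimed to reproduce it"
            ),
        },
    }


def evaluate(
    table: PairedTable,
    ref: ReferenceProfile,
    level: float = 0.95,
    continuity_correction: bool = True,
    clamp: bool = False,
) -> dict:
    """Full evaluation document: both columns, kappa, flags, provenance."""
    profile = naive_profile(table, level, continuity_correction)
    adjusted = adjusted_report(table, ref, clamp=clamp)
    return {
        "config": {
            "alpha": ref.alpha,
            "beta": ref.beta,
            "level": level,
            "continuity_correction": continuity_correction,
            "clamp": clamp,
        },
        "table": table.to_dict(),
        "n": table.n,
        "unadjusted": profile.to_dict(),
        "adjusted": adjusted.to_dict(),
        "kappa": cohen_kappa(table),
        "not_reproduced": known_discrepancies(),
    }


def _fmt(value: Optional[float], decimals: int, scale: float = 1.0) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return "undefined"
    return f"{round_half_up(scale * value, decimals):.{decimals}f}"


def render_text(document: dict) -> str:
    """Two-column indicator table from an ``evaluate`` document."""
    unadj = document["unadjusted"]
    adj = document["adjusted"]

    def ci(estimate: dict, decimals: int, scale: float) -> str:
        if estimate["method"] == "none":
            return ""
        return (
            f"{_fmt(estimate['lower'], decimals, scale)}-"
            f"{_fmt(estimate['upper'], decimals, scale)}"
        )

    # (label, unadjusted key, adjusted key, decimals, scale)
    spec_rows = [
        ("Sensitivity (%)", "sensitivity", "sensitivity", 1, 100.0),
        ("Specificity (%)", "specificity", "specificity", 1, 100.0),
        ("Validity index (%)", "validity_index", "validity_index", 1, 100.0),
        ("Predictive value + (%)", "ppv", "ppv", 1, 100.0),
        ("Predictive value - (%)", "npv", "npv", 1, 100.0),
        ("Prevalence (%)", "prevalence", "prevalence", 1, 100.0),
        ("Youden index", "youden", "youden", 1, 1.0),
        ("Likelihood ratio +", "lr_pos", "lr_pos", 1, 1.0),
        ("Likelihood ratio -", "lr_neg", "lr_neg", 2, 1.0),
    ]
    lines = [
        f"{'Parameter':<24}{'Unadjusted':>12}  {'95% CI':>14}  {'Adjusted':>10}",
    ]
    for label, u_key, a_key, decimals, scale in spec_rows:
        estimate = unadj[u_key]
        lines.append(
            f"{label:<24}{_fmt(estimate['point'], decimals, scale):>12}  "
            f"{ci(estimate, decimals, scale):>14}  {_fmt(adj[a_key], decimals, scale):>10}"
        )
    lines.append(
        f"{'Post-test probability':<24}{'':>12}  {'':>14}  "
        f"{_fmt(adj['post_test_probability'], 1, 100.0):>10}"
    )
    lines.append(f"{'Kappa':<24}{_fmt(document['kappa'], 2):>12}")
    if adj["flags"]:
        lines.append("")
        lines.extend(f"warning: {flag}" for flag in adj["flags"])
    lines.append("")
    lines.append("Not reproduced from the source study (documented, not skipped):")
    for key, entry in document["not_reproduced"].items():
        lines.append(f"  {key}: reported {entry['reported']} -- {entry['note']}")
    return "\n".join(lines)


def to_json(document: dict) -> str:
    return json.dumps(document, indent=2, sort_keys=True) + "\n"


def from_json(text: str) -> dict:
    return json.loads(text)
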