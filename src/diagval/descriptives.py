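"""Descriptive tallies with explicit missing-value denominators.

Percentages are always reported over the number of records that actually
answered (missing excluded), never silently over the enrolled total, and
each row carries the denominator it used.  Rounding is half-up to one
decimal, shared with the rest of the package.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

from .fixtures import (
    AVOID_REASONS,
    DEVICES,
    FINDING_CATEGORIES,
    FindingsRecord,
    SurveyRecord,
)
from .rounding import round_half_up


@dataclass(frozen=True)
class TallyRow:
    """One category's count within one group (a device or a question)."""

    group: str
    category: str
    count: int
    denominator: int
    percent: Optional[float]  # None when the denominator is zero
    missing: int


@dataclass(frozen=True)
class TallyReport:
    rows: tuple[TallyRow, ...]

    def get(self, group: str, category: str) -> TallyRow:
        for row in self.rows:
            if row.group == group and row.category == category:
                return row
        raise KeyError((group, category))

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "group": row.group,
                    "category": row.category,
                    "count": row.count,
                    "denominator": row.denominator,
                    "percent": row.percent,
                    "missing": row.missing,
                }
                for row in self.rows
            ]
        }

    def render_text(self) -> str:
        lines = [f"{'group':<14}{'category':<22}{'n':>6}  {'%':>6}  {'denom':>6}  {'miss':>4}"]
        for row in self.rows:
            pct = "--" if row.percent is None else f"{row.percent:.1f}"
            lines.append(
                f"{row.group:<14}{row.category:<22}{row.count:>6}  {pct:>6}  "
                f"{row.denominator:>6}  {row.missing:>4}"
            )
        return "\n".join(lines)


def _pct(count: int, denominator: int) -> Optional[float]:
    if denominator == 0:
        return None
    return round_half_up(100.0 * count / denominator, 1)


def tally_findings(
    records: Sequence[FindingsRecord], denominator: int
) -> TallyReport:
    """Per-device positive counts and percentages over ``denominator`` events."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    for rec in records:
        if rec.device not in DEVICES:
            raise ValueError(f"unknown device {rec.device!r}")
    rows = []
    for device in DEVICES:
        device_records = [rec for rec in records if rec.device == device]
        for category in FINDING_CATEGORIES:
            count = sum(getattr(rec, category) for rec in device_records)
            rows.append(
                TallyRow(device, category, count, denominator, _pct(count, denominator), 0)
            )
    return TallyReport(tuple(rows))


def tally_survey(records: Sequence[SurveyRecord]) -> TallyReport:
    """Per-question tallies; each question's denominator is its respondents."""
    rows: list[TallyRow] = []

    def binary_question(group: str, attr: str) -> None:
        answered = [getattr(rec, attr) for rec in records if getattr(rec, attr) is not None]
        missing = len(records) - len(answered)
        denominator = len(answered)
        for category, value in (("yes", True), ("no", False)):
            count = sum(1 for ans in answered if ans is value)
            rows.append(
                TallyRow(group, category, count, denominator, _pct(count, denominator), missing)
            )

    def choice_question(group: str, attr: str, categories: Sequence[str]) -> None:
        answered = [getattr(rec, attr) for rec in records if getattr(rec, attr) is not None]
        missing = len(records) - len(answered)
        denominator = len(answered)
        counts = Counter(answered)
        for category in categories:
            count = counts.get(category, 0)
            rows.append(
                TallyRow(group, category, count, denominator, _pct(count, denominator), missing)
            )

    binary_question("comfortable_screening", "comfortable_screening")
    binary_question("easy_to_use", "easy_to_use")
    observed_discomfort = sorted(
        {rec.discomfort for rec in records if rec.discomfort is not None}
    ) or ["none"]
    choice_question("discomfort", "discomfort", observed_discomfort)
    choice_question("avoid_reason", "avoid_reason", AVOID_REASONS)
    return TallyReport(tuple(rows))
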