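"""Packaged study fixtures, rebuilt deterministically at call time.

The validation study this package re-analyses printed only rounded
summaries, marginal tallies and survey percentages — never unit-level
data.  These fixtures reconstruct datasets exactly consistent with every
printed count:

* ``study_fixture_table`` — the unique 2x2 table recovered from the
  printed unadjusted sensitivity/specificity/prevalence at N = 340.
* ``findings_fixture`` — 340 breast events x 2 devices with the printed
  per-device margins for density, cyst/mass/tumor-like and calcification
  findings.
* ``survey_fixture`` — 170 participants with the printed acceptability
  tallies and exactly one missing response per survey item.

Only the margins are constrained by the study; any joint structure
(which breasts carry which combinations of findings, which participant
skipped each question) is SYNTHETIC.  Flags are assigned
maximally-overlapping from the start of the unit list, so e.g. every
breast dense under the mammogram is also dense under the index device.
The fixtures are pure functions of nothing: regeneration is
byte-identical by construction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .tables import PairedTable, SummaryConstraints, reconstruct_from_summary

N_BREAST_EVENTS = 340
N_PARTICIPANTS = 170

DEVICES = ("mammogram", "plb")
FINDING_CATEGORIES = ("dense", "cyst_mass_tumor", "calcification")
AVOID_REASONS = ("dislike", "fear_hurt", "anxiety")

# Printed per-device positive counts over 340 breast events.
_FINDING_COUNTS = {
    "mammogram": {"dense": 248, "cyst_mass_tumor": 19, "calcification": 21},
    "plb": {"dense": 266, "cyst_mass_tumor": 22, "calcification": 32},
}

# Printed survey tallies over 169 respondents (one missing per item).
_SURVEY_COUNTS = {
    "comfortable_yes": 164,
    "easy_yes": 169,
    "discomfort_none": 169,
    "avoid": {"dislike": 16, "fear_hurt": 119, "anxiety": 34},
}


def study_fixture_table() -> PairedTable:
    """The study's 2x2 table, recovered from its printed rounded summaries.

    At N = 340 with unadjusted sensitivity 86.3%, specificity 68.9% and
    prevalence 68.8% (one printed decimal), exactly one integer table is
    consistent: (a, b, c, d) = (202, 33, 32, 73).  It is recomputed here
    by exhaustive search rather than hard-coded.
    """
    candidates = reconstruct_from_summary(
        SummaryConstraints(n=340, se_pct=86.3, sp_pct=68.9, prev_pct=68.8, decimals=1)
    )
    assert len(candidates) == 1, "study summaries no longer reconstruct uniquely"
    return candidates[0]


@dataclass(frozen=True)
class FindingsRecord:
    """One device's reading of one breast event (flags, not diagnoses)."""

    unit_id: str
    device: str
    dense: bool
    cyst_mass_tumor: bool
    calcification: bool

    def __post_init__(self) -> None:
        if self.device not in DEVICES:
            raise ValueError(f"device must be one of {DEVICES}, got {self.device!r}")


@dataclass(frozen=True)
class SurveyRecord:
    """One participant's acceptability responses; None is a missing answer."""

    participant_id: str
    comfortable_screening: Optional[bool]
    easy_to_use: Optional[bool]
    discomfort: Optional[str]
    avoid_reason: Optional[str]

    def __post_init__(self) -> None:
        if self.avoid_reason is not None and self.avoid_reason not in AVOID_REASONS:
            raise ValueError(
                f"avoid_reason must be one of {AVOID_REASONS}, got {self.avoid_reason!r}"
            )


def _event_ids() -> list[str]:
    ids = []
    for participant in range(1, N_PARTICIPANTS + 1):
        for side in ("R", "L"):
            ids.append(f"P{participant:03d}-{side}")
    return ids


def findings_fixture() -> list[FindingsRecord]:
    """340 breast events read by both devices, matching the printed margins.

    Co-occurrence of findings within and across devices is synthetic:
    each flag is set on the first k events in a fixed unit order, where k
    is the printed count, giving maximal overlap between devices.
    """
    ids = _event_ids()
    records = []
    for device in DEVICES:
        counts = _FINDING_COUNTS[device]
        for position, unit_id in enumerate(ids):
            records.append(
                FindingsRecord(
                    unit_id=unit_id,
                    device=device,
                    dense=position < counts["dense"],
                    cyst_mass_tumor=position < counts["cyst_mass_tumor"],
                    calcification=position < counts["calcification"],
                )
            )
    return records


def survey_fixture() -> list[SurveyRecord]:
    """170 participants; the last one answered nothing (synthetic choice).

    This yields exactly one missing value per item and 169 respondents,
    with 164 comfortable-with-screening, unanimous ease-of-use and
    no-discomfort answers, and avoid-a-mammogram reasons split
    16 / 119 / 34 (dislike / fear of pain / anxiety).
    """
    records = []
    avoid_plan = (
        ["dislike"] * _SURVEY_COUNTS["avoid"]["dislike"]
        + ["fear_hurt"] * _SURVEY_COUNTS["avoid"]["fear_hurt"]
        + ["anxiety"] * _SURVEY_COUNTS["avoid"]["anxiety"]
    )
    for participant in range(1, N_PARTICIPANTS + 1):
        pid = f"P{participant:03d}"
        if participant == N_PARTICIPANTS:
            records.append(SurveyRecord(pid, None, None, None, None))
            continue
        position = participant - 1  # 0-based among the 169 respondents
        records.append(
            SurveyRecord(
                participant_id=pid,
                comfortable_screening=position < _SURVEY_COUNTS["comfortable_yes"],
                easy_to_use=True,
                discomfort="none",
                avoid_reason=avoid_plan[position],
            )
        )
    return records


# ---------------------------------------------------------------------------
# Delimited writers (missing answers serialize as empty fields)


def write_findings(records: Iterable[FindingsRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["unit_id", "device", *FINDING_CATEGORIES])
        for rec in records:
            writer.writerow(
                [
                    rec.unit_id,
                    rec.device,
                    int(rec.dense),
                    int(rec.cyst_mass_tumor),
                    int(rec.calcification),
                ]
            )


def read_findings(path: str | Path) -> list[FindingsRecord]:
    records = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            records.append(
                FindingsRecord(
                    unit_id=row["unit_id"],
                    device=row["device"],
                    dense=bool(int(row["dense"])),
                    cyst_mass_tumor=bool(int(row["cyst_mass_tumor"])),
                    calcification=bool(int(row["calcification"])),
                )
            )
    return records


def write_survey(records: Iterable[SurveyRecord], path: str | Path) -> None:
    def cell(value) -> str:
        if value is None:
            return ""
        if isinstance(value, bool):
            return str(int(value))
        return value

    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            [
                "participant_id",
                "comfortable_screening",
                "easy_to_use",
                "discomfort",
                "avoid_reason",
            ]
        )
        for rec in records:
            writer.writerow(
                [
                    rec.participant_id,
                    cell(rec.comfortable_screening),
                    cell(rec.easy_to_use),
                    cell(rec.discomfort),
                    cell(rec.avoid_reason),
                ]
            )


def read_survey(path: str | Path) -> list[SurveyRecord]:
    def opt_bool(token: str) -> Optional[bool]:
        return None if token == "" else bool(int(token))

    records = []
    with Path(path).open(newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            records.append(
                SurveyRecord(
                    participant_id=row["participant_id"],
                    comfortable_screening=opt_bool(row["comfortable_screening"]),
                    easy_to_use=opt_bool(row["easy_to_use"]),
                    discomfort=row["discomfort"] or None,
                    avoid_reason=row["avoid_reason"] or None,
                )
            )
    return records
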