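"""The 2x2 paired-test table and its constructors.

A paired diagnostic study cross-classifies every unit by an index test
(the new test under evaluation) and a reference test (the comparator):

              reference +   reference -
    index +        a             b
    index -        c             d

``PairedTable`` is the computational atom of the whole package.  It can be
built three ways: directly from cell counts, by tallying per-unit
``SubjectRecord`` data (``table_from_records``), or — when a study reports
only rounded summary percentages — by exhaustive reconstruction of every
integer table consistent with those summaries (``reconstruct_from_summary``).

Units here are breasts, not persons: each breast is an independent event
and no intra-person correlation is modelled.
"""

from __future__ import annotations

import csv
import json
import operator
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import (
    DuplicateUnitError,
    InconsistentSummaryError,
    NoRecordsError,
)
from .rounding import round_half_up

SIDES = ("left", "right")

_TRUE_TOKENS = frozenset({"1", "pos", "positive", "true"})
_FALSE_TOKENS = frozenset({"0", "neg", "negative", "false"})


def parse_binary(token: str) -> bool:
    """Parse a binary test result from its textual encoding.

    Accepted (case-insensitive): 1/0, pos/neg, positive/negative,
    true/false.  Anything else is an error, never a guess.
    """
    key = str(token).strip().lower()
    if key in _TRUE_TOKENS:
        return True
    if key in _FALSE_TOKENS:
        return False
    raise ValueError(f"unrecognized binary value {token!r}")


@dataclass(frozen=True)
class PairedTable:
    """Cross-classification of index vs reference results.

    a: index+ and reference+;  b: index+ and reference-;
    c: index- and reference+;  d: index- and reference-.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if isinstance(value, bool):
                raise ValueError(f"cell {name} must be an integer count, got bool")
            try:
                value = operator.index(value)
            except TypeError:
                raise ValueError(
                    f"cell {name} must be an integer count, got {value!r}"
                ) from None
            if value < 0:
                raise ValueError(f"cell {name} must be non-negative, got {value}")
            object.__setattr__(self, name, int(value))
        if self.n == 0:
            raise ValueError("empty table: total N must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def ref_pos(self) -> int:
        """Reference-positive margin a+c."""
        return self.a + self.c

    @property
    def ref_neg(self) -> int:
        return self.b + self.d

    @property
    def index_pos(self) -> int:
        return self.a + self.b

    @property
    def index_neg(self) -> int:
        return self.c + self.d

    def swap_labels(self) -> "PairedTable":
        """Relabel positive<->negative on BOTH tests simultaneously."""
        return PairedTable(self.d, self.c, self.b, self.a)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, payload: dict) -> "PairedTable":
        missing = {"a", "b", "c", "d"} - payload.keys()
        if missing:
            raise ValueError(f"table JSON missing cells: {sorted(missing)}")
        return cls(*(int(payload[k]) for k in "abcd"))

    @classmethod
    def from_json(cls, text: str) -> "PairedTable":
        payload = json.loads(text)
        if not isinstance(payload, dict):
            raise ValueError("table JSON must be an object with keys a,b,c,d")
        return cls.from_dict(payload)


@dataclass(frozen=True)
class ReferenceProfile:
    """Known operating characteristics of the imperfect reference test.

    alpha: reference sensitivity, beta: reference specificity, both
    fractions in (0, 1].  Identifiability of the correction requires
    alpha + beta > 1 (the reference must be better than coin-flipping),
    because alpha + beta - 1 appears in the correction's denominators.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha", "beta"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.alpha + self.beta <= 1.0:
            raise ValueError(
                "reference uninformative: alpha + beta must exceed 1 "
                f"(got {self.alpha} + {self.beta})"
            )

    @property
    def is_perfect(self) -> bool:
        return self.alpha == 1.0 and self.beta == 1.0


@dataclass(frozen=True)
class SubjectRecord:
    """One breast-level observation.

    ``true_status`` is only ever known for simulated data; real cohorts
    carry None there.
    """

    unit_id: str
    side: str
    index_result: bool
    reference_result: bool
    true_status: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")


def table_from_records(records: Sequence[SubjectRecord]) -> PairedTable:
    """Tally per-unit records into a PairedTable.

    Raises NoRecordsError for an empty sequence and DuplicateUnitError if
    any (unit_id, side) pair occurs twice.
    """
    records = list(records)
    if not records:
        raise NoRecordsError("no admissible records")
    seen: set[tuple[str, str]] = set()
    a = b = c = d = 0
    for rec in records:
        key = (rec.unit_id, rec.side)
        if key in seen:
            raise DuplicateUnitError(f"duplicate unit {key!r}")
        seen.add(key)
        if rec.index_result and rec.reference_result:
            a += 1
        elif rec.index_result:
            b += 1
        elif rec.reference_result:
            c += 1
        else:
            d += 1
    return PairedTable(a, b, c, d)


@dataclass(frozen=True)
class SummaryConstraints:
    """Printed rounded summaries from which a table is to be reconstructed.

    se_pct, sp_pct, prev_pct are the rounded unadjusted sensitivity,
    specificity and prevalence (reference-positive fraction) in percent;
    decimals is the number of decimal places they were printed with.
    """

    n: int
    se_pct: float
    sp_pct: float
    prev_pct: float
    decimals: int = 1

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"N must be positive, got {self.n}")
        if self.decimals < 0:
            raise ValueError("decimals must be non-negative")
        for name in ("se_pct", "sp_pct", "prev_pct"):
            value = getattr(self, name)
            if not 0.0 <= value <= 100.0:
                raise ValueError(f"{name} must lie in [0, 100], got {value}")


def summarize_table(table: PairedTable, decimals: int = 1) -> SummaryConstraints:
    """Round a table's Se/Sp/prevalence to printed precision.

    Degenerate margins (no reference-positives or -negatives) report the
    undefined proportion as 0; reconstruct_from_summary treats such
    margins as unconstrained, so the round trip still succeeds.
    """

    def pct(num: int, den: int) -> float:
        return round_half_up(100.0 * num / den, decimals) if den else 0.0

    return SummaryConstraints(
        n=table.n,
        se_pct=pct(table.a, table.ref_pos),
        sp_pct=pct(table.d, table.ref_neg),
        prev_pct=pct(table.ref_pos, table.n),
        decimals=decimals,
    )


def reconstruct_from_summary(constraints: SummaryConstraints) -> list[PairedTable]:
    """Every integer table consistent with rounded printed summaries.

    Exhaustive search over the reference-positive margin n1 in [0, N] and,
    within each margin, over admissible a and d.  The three constraints
    are separable given n1 (prevalence fixes n1; sensitivity constrains a
    within n1; specificity constrains d within N-n1), so the search is
    O(N^2) and runs in well under a second for study-sized N.

    Returns candidates sorted by (a, b).  A margin of zero makes the
    corresponding proportion undefined, which is treated as unconstrained.
    """
    n_total = constraints.n
    dec = constraints.decimals

    def matches(count: int, total: int, target_pct: float) -> bool:
        if total == 0:
            return True
        return round_half_up(100.0 * count / total, dec) == round_half_up(
            target_pct, dec
        )

    candidates: list[PairedTable] = []
    for n1 in range(n_total + 1):
        n2 = n_total - n1
        if not matches(n1, n_total, constraints.prev_pct):
            continue
        a_values = [a for a in range(n1 + 1) if matches(a, n1, constraints.se_pct)]
        if not a_values:
            continue
        d_values = [d for d in range(n2 + 1) if matches(d, n2, constraints.sp_pct)]
        for a in a_values:
            for d in d_values:
                candidates.append(PairedTable(a, n2 - d, n1 - a, d))
    if not candidates:
        raise InconsistentSummaryError(
            "inconsistent summary: no integer table matches the printed values"
        )
    candidates.sort(key=lambda t: (t.a, t.b))
    return candidates


# ---------------------------------------------------------------------------
# Delimited-file interface (CSV, UTF-8, header row)

_COLUMNS = ("unit_id", "side", "index_result", "reference_result", "true_status")


def read_records(path: str | Path) -> list[SubjectRecord]:
    """Read SubjectRecords from a CSV file; errors carry line numbers."""
    path = Path(path)
    records: list[SubjectRecord] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        required = {"unit_id", "side", "index_result", "reference_result"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                truth_token = (row.get("true_status") or "").strip()
                records.append(
                    SubjectRecord(
                        unit_id=row["unit_id"].strip(),
                        side=row["side"].strip().lower(),
                        index_result=parse_binary(row["index_result"]),
                        reference_result=parse_binary(row["reference_result"]),
                        true_status=parse_binary(truth_token) if truth_token else None,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_records(records: Iterable[SubjectRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.unit_id,
                    rec.side,
                    int(rec.index_result),
                    int(rec.reference_result),
                    "" if rec.true_status is None else int(rec.true_status),
                ]
            )
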