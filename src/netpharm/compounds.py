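"""Herb compound tables and the ADME activity screen.

Traditional-medicine network pharmacology starts from a table of candidate
herb compounds annotated with two absorption/drug-likeness descriptors:

* **OB** — oral bioavailability, the percentage of an orally administered
  dose reaching systemic circulation (0-100).
* **DL** — drug-likeness, a dimensionless similarity index to known drugs
  (0-1).

A compound is called *active* when it clears both thresholds
(conventionally OB >= 30 % and DL >= 0.18, both inclusive). Compounds a
study carries along by expert judgement despite failing the screen are
flagged ``manual_add``; they bypass the filter only on request and
typically contribute no targets downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import FormatError, ParseError

__all__ = [
    "CompoundRecord",
    "read_compound_table",
    "adme_filter",
    "per_herb_summary",
    "HerbSummary",
    "DEFAULT_OB_MIN",
    "DEFAULT_DL_MIN",
]

DEFAULT_OB_MIN = 30.0
DEFAULT_DL_MIN = 0.18

_REQUIRED_COLUMNS = ("id", "name", "ob", "dl", "source")

_TRUE_STRINGS = {"true", "1", "yes", "t"}
_FALSE_STRINGS = {"false", "0", "no", "f", ""}


@dataclass(frozen=True)
class CompoundRecord:
    """One screened herb compound (a row of a compound table).

    Attributes
    ----------
    compound_id:
        Stable identifier, e.g. a TCMSP molecule id like ``"MOL002421"``.
    name:
        Free-text compound name.
    ob:
        Oral bioavailability in percent, >= 0.
    dl:
        Drug-likeness index, dimensionless, >= 0.
    herb:
        Source-herb label.
    manual_add:
        True for compounds carried along by expert judgement that should
        bypass the ADME screen only when explicitly requested.
    """

    compound_id: str
    name: str
    ob: float
    dl: float
    herb: str
    manual_add: bool = False

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.ob < 0:
            raise ValueError(f"OB must be >= 0, got {self.ob}")
        if self.dl < 0:
            raise ValueError(f"DL must be >= 0, got {self.dl}")


def _delimiter_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ","}.get(dialect, dialect)
    return "," if path.suffix.lower() == ".csv" else "\t"


def _parse_bool(text: str, row_no: int) -> bool:
    low = text.strip().lower()
    if low in _TRUE_STRINGS:
        return True
    if low in _FALSE_STRINGS:
        return False
    raise ParseError(f"row {row_no}: cannot parse boolean {text!r}")


def read_compound_table(
    path: str | Path, dialect: str | None = None
) -> list[CompoundRecord]:
    """Read a compound table (TSV by default, CSV by extension or dialect).

    The header must name the columns ``id, name, ob, dl, source``
    (case-insensitive, any order); an optional ``manual_add`` boolean
    column is honoured. Row order is preserved. Duplicate compound ids are
    rejected within a herb but allowed across herbs (the same molecule may
    occur in two herbs).

    Raises
    ------
    FormatError
        If a required column is missing.
    ParseError
        If OB/DL are non-numeric, with the offending row number.
    """
    path = Path(path)
    delim = _delimiter_for(path, dialect)
    records: list[CompoundRecord] = []
    seen: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, expected a header row")
        cols = {h.strip().lower(): i for i, h in enumerate(header)}
        for col in _REQUIRED_COLUMNS:
            if col not in cols:
                raise FormatError(f"{path}: missing required column '{col}'")
        manual_idx = cols.get("manual_add")
        for row_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            fields = {c: row[i].strip() for c, i in cols.items() if i < len(row)}
            try:
                ob = float(fields["ob"])
                dl = float(fields["dl"])
            except (KeyError, ValueError):
                raise ParseError(
                    f"{path}: row {row_no}: non-numeric OB/DL in {row!r}"
                )
            manual = False
            if manual_idx is not None and manual_idx < len(row):
                manual = _parse_bool(row[manual_idx], row_no)
            rec = CompoundRecord(
                compound_id=fields["id"],
                name=fields["name"],
                ob=ob,
                dl=dl,
                herb=fields["source"],
                manual_add=manual,
            )
            key = (rec.herb, rec.compound_id)
            if key in seen:
                raise FormatError(
                    f"{path}: row {row_no}: duplicate compound id "
                    f"'{rec.compound_id}' within herb '{rec.herb}'"
                )
            seen.add(key)
            records.append(rec)
    return records


def adme_filter(
    records: Iterable[CompoundRecord],
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
    include_manual: bool = False,
) -> list[CompoundRecord]:
    """Keep compounds with ``ob >= ob_min`` and ``dl >= dl_min`` (inclusive).

    Input order is preserved; an empty result is legal. With
    ``include_manual=True``, records flagged ``manual_add`` pass regardless
    of their descriptors (the expert-judgement bypass).
    """
    out = []
    for rec in records:
        if (rec.ob >= ob_min and rec.dl >= dl_min) or (
            include_manual and rec.manual_add
        ):
            out.append(rec)
    return out


@dataclass(frozen=True)
class HerbSummary:
    """Per-herb compound count and the compound with maximal OB."""

    herb: str
    count: int
    best: CompoundRecord = field(repr=False)

    @property
    def max_ob(self) -> float:
        return self.best.ob


def per_herb_summary(
    records: Iterable[CompoundRecord],
) -> Mapping[str, HerbSummary]:
    """Summarise records per herb: count and max-OB compound.

    Ties on OB are broken by first occurrence in the input. Raises
    ``ValueError`` on an empty input.
    """
    summaries: dict[str, HerbSummary] = {}
    for rec in records:
        prev = summaries.get(rec.herb)
        if prev is None:
            summaries[rec.herb] = HerbSummary(rec.herb, 1, rec)
        else:
            best = rec if rec.ob > prev.best.ob else prev.best
            summaries[rec.herb] = HerbSummary(rec.herb, prev.count + 1, best)
    if not summaries:
        raise ValueError("per_herb_summary requires at least one record")
    return summaries
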