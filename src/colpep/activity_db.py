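"""Peptide-activity database: a local stand-in for a bioactive-peptide table.

The database associates short peptide sequences with bioactivity codes
(``ah`` = ACE inhibitor, ``dpp`` = DPP-IV inhibitor, ``dpp3``, ``at``, ``am``,
``re``, ``ao``, ...), optionally carrying literature IC50 metadata. The on-disk
format is a UTF-8 TSV with a header row::

    peptide  activity_code  activity_name  ic50_value  ic50_unit  reference

Only the first two columns are required. A small built-in fixture ships the
nine ACE/DPP-IV-inhibiting peptides released in silico from collagen type I
chains, with their literature IC50 values where reported. Users can plug in
any snapshot of a full bioactive-peptide database in the same dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .sequence_io import canonicalize_sequence

logger = logging.getLogger("colpep")

_COLUMNS = ("peptide", "activity_code", "activity_name", "ic50_value", "ic50_unit", "reference")


@dataclass(frozen=True)
class ActivityRecord:
    """One peptide ↔ activity association with optional IC50 metadata."""

    peptide: str
    activity_code: str
    activity_name: str = ""
    ic50_value: float | None = None
    ic50_unit: str | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if canonicalize_sequence(self.peptide, "strict") != self.peptide:
            raise ValueError(f"peptide {self.peptide!r} is not canonical")
        if not self.activity_code:
            raise ValueError("activity_code must be non-empty")
        if self.ic50_value is not None and self.ic50_value <= 0:
            raise ValueError(f"ic50_value must be positive, got {self.ic50_value}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.peptide, self.activity_code)


class PeptideActivityDB:
    """A validated set of :class:`ActivityRecord` s indexed by activity code.

    Activity codes are case-sensitive. ``(peptide, activity_code)`` pairs are
    unique; duplicates passed to the constructor are collapsed with a warning.
    """

    def __init__(self, records: "list[ActivityRecord] | tuple[ActivityRecord, ...]" = ()):
        seen: dict[tuple[str, str], ActivityRecord] = {}
        dups = 0
        for rec in records:
            if rec.key in seen:
                dups += 1
            seen[rec.key] = rec
        if dups:
            logger.warning("collapsed %d duplicate (peptide, activity_code) record(s)", dups)
        self._records: tuple[ActivityRecord, ...] = tuple(seen.values())
        index: dict[str, set[str]] = {}
        for rec in self._records:
            index.setdefault(rec.activity_code, set()).add(rec.peptide)
        self._index = {code: frozenset(peps) for code, peps in index.items()}

    @property
    def records(self) -> tuple[ActivityRecord, ...]:
        return self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def activity_codes(self) -> tuple[str, ...]:
        """All activity codes present, sorted."""
        return tuple(sorted(self._index))

    def peptides(self) -> frozenset[str]:
        """The distinct peptide sequences in the database."""
        return frozenset(rec.peptide for rec in self._records)

    def peptides_for_activity(self, activity_code: str) -> frozenset[str]:
        """Peptides carrying ``activity_code``; unknown codes yield the empty set."""
        return self._index.get(activity_code, frozenset())

    def records_for_peptide(self, peptide: str) -> tuple[ActivityRecord, ...]:
        return tuple(rec for rec in self._records if rec.peptide == peptide)


def load_activity_table(path: str | Path) -> PeptideActivityDB:
    """Load a TSV activity table (see module docstring for the dialect).

    Invalid peptide strings are rejected with the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"peptide", "activity_code"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    records = []
    for row in df.itertuples(index=True):
        line_no = row.Index + 2  # 1-based, after the header line
        try:
            rec = ActivityRecord(
                peptide=row.peptide,
                activity_code=row.activity_code,
                activity_name=getattr(row, "activity_name", ""),
                ic50_value=float(row.ic50_value) if getattr(row, "ic50_value", "") else None,
                ic50_unit=getattr(row, "ic50_unit", "") or None,
                reference=getattr(row, "reference", "") or None,
            )
        except ValueError as exc:
            raise ValueError(f"{path}, line {line_no}: {exc}") from exc
        records.append(rec)
    return PeptideActivityDB(records)


def export_activity_table(db: PeptideActivityDB, path: str | Path) -> None:
    """Write ``db`` back to the TSV dialect read by :func:`load_activity_table`."""
    rows = [
        {
            "peptide": r.peptide,
            "activity_code": r.activity_code,
            "activity_name": r.activity_name,
            "ic50_value": "" if r.ic50_value is None else r.ic50_value,
            "ic50_unit": r.ic50_unit or "",
            "reference": r.reference or "",
        }
        for r in db.records
    ]
    pd.DataFrame(rows, columns=list(_COLUMNS)).to_csv(path, sep="\t", index=False)


def builtin_fixture() -> PeptideActivityDB:
    """The bundled database of nine collagen-derived ACE/DPP-IV inhibitors.

    Contains GF, SF, QF, DF, PGL, TF, GR and RL plus DR with their ``ah``
    (ACE-inhibitor) and/or ``dpp`` (DPP-IV-inhibitor) annotations and
    literature IC50 metadata where reported (e.g. PGL, ah, IC50 = 13.93 uM).
    """
    ref = resources.files("colpep.data").joinpath("activity_fixture.tsv")
    with resources.as_file(ref) as path:
        return load_activity_table(path)
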