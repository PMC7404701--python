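"""Quantitative occurrence and release parameters for bioactive fragments.

For a protein of N residues and an activity code:

* ``a`` — number of (possibly overlapping) occurrences, counted over all
  database peptides carrying the code, with multiplicity per start position;
* ``A = a / N`` — frequency of occurrence: the protein's *potential* as a
  source of peptides with that activity;
* ``d`` — number of digest fragments whose full sequence equals a database
  peptide with the code (multiplicity across fragment positions);
* ``A_E = d / N`` — frequency of release by the selected enzyme(s);
* ``W = A_E / A`` — relative frequency of release, the released share of the
  potential; undefined when ``A == 0``.

``A`` values are binned: major (A ≥ 0.500), moderate (0.100 ≤ A < 0.500),
minor (0 < A < 0.100), none (A == 0).

All frequencies are kept as exact rationals; report writers round to three
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Real
from typing import Sequence

from .activity_db import PeptideActivityDB
from .digestion import DigestResult
from .sequence_io import ProteinRecord

BIN_MAJOR = Fraction(1, 2)
BIN_MODERATE = Fraction(1, 10)


@dataclass(frozen=True)
class ActivityProfile:
    """Occurrence counts of one activity in one protein (parameter A)."""

    protein_id: str
    activity_code: str
    a_count: int
    A: Fraction
    bin: str


@dataclass(frozen=True)
class ReleaseProfile:
    """Release counts of one activity for one protein × enzyme-set digest.

    ``W`` is ``None`` (reported blank) when the protein has no occurrences of
    the activity (A == 0).
    """

    protein_id: str
    enzymes: tuple[str, ...]
    activity_code: str
    d_count: int
    A_E: Fraction
    W: Fraction | None


def count_occurrences(protein_sequence: str, peptide: str) -> int:
    """Number of (possibly overlapping) start positions of ``peptide``."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    count = 0
    start = protein_sequence.find(peptide)
    while start != -1:
        count += 1
        start = protein_sequence.find(peptide, start + 1)
    return count


def classify_A(A: "Real | Fraction") -> str:
    """Deterministic major/moderate/minor/none bin of an A value."""
    if A < 0:
        raise ValueError(f"A must be non-negative, got {A}")
    if A >= BIN_MAJOR:
        return "major"
    if A >= BIN_MODERATE:
        return "moderate"
    if A > 0:
        return "minor"
    return "none"


def profile_occurrence(
    protein: ProteinRecord, db: PeptideActivityDB, include_zero: bool = False
) -> list[ActivityProfile]:
    """Parameter A for every activity code in ``db`` against ``protein``.

    Activities with no occurrences are omitted unless ``include_zero`` is set
    (reports drop them; they remain available on request). A peptide listed
    under k activity codes contributes to all k profiles.
    """
    n = protein.n_residues
    profiles = []
    for code in db.activity_codes():
        a_count = sum(
            count_occurrences(protein.sequence, pep)
            for pep in sorted(db.peptides_for_activity(code))
        )
        if a_count == 0 and not include_zero:
            continue
        A = Fraction(a_count, n)
        profiles.append(
            ActivityProfile(
                protein_id=protein.id,
                activity_code=code,
                a_count=a_count,
                A=A,
                bin=classify_A(A),
            )
        )
    return profiles


def profile_release(
    protein: ProteinRecord,
    digest: DigestResult,
    db: PeptideActivityDB,
    occurrence: Sequence[ActivityProfile],
) -> list[ReleaseProfile]:
    """Parameters A_E and W for every activity code, given a completed digest.

    A fragment is counted for an activity iff its *full* sequence exactly
    equals a database peptide carrying the code (substring containment does
    not count: only released fragments match), with multiplicity across
    fragment positions.
    """
    if digest.protein_id != protein.id:
        raise ValueError(
            f"digest belongs to {digest.protein_id!r}, not {protein.id!r}"
        )
    n = protein.n_residues
    a_by_code = {p.activity_code: p.A for p in occurrence}
    profiles = []
    for code in db.activity_codes():
        peps = db.peptides_for_activity(code)
        d_count = sum(1 for frag, _, _ in digest.fragments if frag in peps)
        A_E = Fraction(d_count, n)
        A = a_by_code.get(code, Fraction(0))
        W = A_E / A if A > 0 else None
        profiles.append(
            ReleaseProfile(
                protein_id=protein.id,
                enzymes=digest.enzymes,
                activity_code=code,
                d_count=d_count,
                A_E=A_E,
                W=W,
            )
        )
    return profiles


# -- report formatting helpers -------------------------------------------------


def format_frequency(value: Fraction | None) -> str:
    """Three-decimal report format; values rounding to 0.000 (and undefined
    W) become blank cells, mirroring how release tables omit sub-0.001
    frequencies."""
    if value is None:
        return ""
    text = f"{float(value):.3f}"
    return "" if text == "0.000" else text


def sort_occurrence(profiles: Sequence[ActivityProfile]) -> list[ActivityProfile]:
    """Descending A, then activity code, for deterministic tables."""
    return sorted(profiles, key=lambda p: (-p.A, p.activity_code))


def sort_release(profiles: Sequence[ReleaseProfile]) -> list[ReleaseProfile]:
    """Descending A_E, then activity code, for deterministic tables."""
    return sorted(profiles, key=lambda p: (-p.A_E, p.activity_code))
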