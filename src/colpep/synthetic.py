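"""Collagen-like synthetic proteins with planted bioactive motifs.

The generator emulates the primary-structure signature of collagen α-chains —
an uninterrupted run of G-X-Y triplets with proline-rich X/Y positions
(hydroxyproline is modelled as plain proline) — and plants copies of known
bioactive motifs at seeded, triplet-aligned positions. Because every expected
output (occurrence counts, release counts, DH_t) is recomputed at generation
time by a naive brute-force pass that is independent of the digestion and
profiling engines, fixtures built here have analytically known answers and
serve as exact oracles for the pipeline.

Flank modes:

* ``cuttable`` — each planted copy is flanked so that the first requested
  enzyme set cuts exactly at its boundaries (the preceding residue is drawn
  from a rule's P1 set; the copy is released as an exact fragment, so
  W == 1 when there are no accidental occurrences);
* ``inert`` — flanking residues are chosen outside every P1 set of the
  requested enzymes, so the motif's N-terminal boundary is never cut and the
  exact motif is not released.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

from .activity_db import ActivityRecord, PeptideActivityDB, export_activity_table
from .digestion import WINDOW_OFFSETS, EnzymeSpec, default_ruleset, resolve_enzymes
from .sequence_io import AMINO_ACIDS, ProteinRecord, write_fasta

#: X/Y-position composition approximating collagen: proline-dominated with
#: minor Ala/Glu/Ser/Gln/Arg/Lys/Asp/Leu/Phe, so pepsin/trypsin site densities
#: sit in the low-DH_t regime typical of collagen chains.
DEFAULT_COMPOSITION: Mapping[str, float] = {
    "P": 10.0,
    "A": 3.0,
    "E": 2.0,
    "S": 2.0,
    "Q": 2.0,
    "R": 2.0,
    "K": 1.0,
    "D": 1.0,
    "L": 1.0,
    "F": 1.0,
}

DEFAULT_ENZYME_SETS: tuple[tuple[str, ...], ...] = (
    ("pepsin",),
    ("trypsin",),
    ("pepsin", "trypsin"),
)

_MAX_PLANT_RETRIES = 200


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic fixture. Seeds are mandatory; the module
    never touches global random state."""

    n_triplets: int
    seed: int
    composition: Mapping[str, float] | None = None
    motifs: tuple[tuple[str, str, int], ...] = ()  # (peptide, activity_code, copies)
    flank_mode: str = "cuttable"

    def __post_init__(self) -> None:
        if self.flank_mode not in ("cuttable", "inert"):
            raise ValueError(f"unknown flank_mode {self.flank_mode!r}")
        comp = self.composition
        if comp is not None:
            bad = set(comp) - AMINO_ACIDS
            if bad:
                raise ValueError(f"non-standard residue(s) in composition: {sorted(bad)}")
            if any(w < 0 for w in comp.values()) or not any(w > 0 for w in comp.values()):
                raise ValueError("composition weights must be non-negative with at least one positive")
        for pep, code, copies in self.motifs:
            if copies < 1:
                raise ValueError(f"motif {pep!r}: copies must be >= 1")
            if not code:
                raise ValueError(f"motif {pep!r}: empty activity code")
            if not pep or set(pep) - AMINO_ACIDS:
                raise ValueError(f"motif {pep!r} is not a canonical peptide")
            if set(pep) == {"G"}:
                raise ValueError(
                    f"motif {pep!r} is a glycine-only run; it would self-overlap "
                    "with the G-X-Y frame"
                )
        object.__setattr__(self, "motifs", tuple(self.motifs))


@dataclass(frozen=True)
class GroundTruth:
    """A planted protein plus brute-force expected parameters.

    Expected values are computed by the naive oracle in this module, never by
    the digestion/profiling engines under test.
    """

    protein: ProteinRecord
    planted_positions: Mapping[str, tuple[int, ...]]
    expected_A: Mapping[str, Fraction]
    expected_AE: Mapping[tuple[str, tuple[str, ...]], Fraction]
    expected_DHt: Mapping[tuple[str, ...], Fraction]


# -- naive oracle (kept deliberately independent of digestion/profiling) ------


def oracle_count(sequence: str, peptide: str) -> int:
    """Brute-force overlapping substring count."""
    k = len(peptide)
    return sum(1 for i in range(len(sequence) - k + 1) if sequence[i : i + k] == peptide)


def _oracle_bond_cut(sequence: str, bond: int, enzymes: Sequence[EnzymeSpec]) -> bool:
    for enzyme in enzymes:
        for rule in enzyme.rules:
            satisfied = True
            for pos, constraint in rule.window.items():
                j = bond + WINDOW_OFFSETS[pos]
                inside = 0 <= j < len(sequence)
                if constraint.kind == "allow":
                    if not (inside and sequence[j] in constraint.residues):
                        satisfied = False
                        break
                else:
                    if inside and sequence[j] in constraint.residues:
                        satisfied = False
                        break
            if satisfied:
                return True
    return False


def oracle_cut_sites(sequence: str, enzymes: Sequence[EnzymeSpec]) -> list[int]:
    """Brute-force per-bond scan over every rule window."""
    return [i for i in range(len(sequence) - 1) if _oracle_bond_cut(sequence, i, enzymes)]


def oracle_fragments(sequence: str, cut_sites: Sequence[int]) -> list[str]:
    out, prev = [], 0
    for site in cut_sites:
        out.append(sequence[prev : site + 1])
        prev = site + 1
    out.append(sequence[prev:])
    return out


# -- generation ----------------------------------------------------------------


def generate_collagen_like(spec: SyntheticSpec) -> ProteinRecord:
    """A deterministic G-X-Y repeat sequence of ``spec.n_triplets`` triplets."""
    if spec.n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    comp = dict(spec.composition or DEFAULT_COMPOSITION)
    residues = sorted(r for r, w in comp.items() if w > 0)
    weights = [comp[r] for r in residues]
    rng = random.Random(f"colpep-gxy-{spec.seed}")
    triplets = (
        "G" + "".join(rng.choices(residues, weights=weights, k=2))
        for _ in range(spec.n_triplets)
    )
    return ProteinRecord(id=f"synthetic-{spec.seed}", sequence="".join(triplets))


def make_synthetic_db(spec: SyntheticSpec) -> PeptideActivityDB:
    """Activity table containing exactly the planted motifs with their codes."""
    return PeptideActivityDB(
        [
            ActivityRecord(peptide=pep, activity_code=code, activity_name="synthetic")
            for pep, code, _ in spec.motifs
        ]
    )


def _grouped_motifs(spec: SyntheticSpec) -> dict[str, int]:
    """Copies to plant per distinct peptide (max over its activity rows)."""
    copies: dict[str, int] = {}
    for pep, _, c in spec.motifs:
        copies[pep] = max(copies.get(pep, 0), c)
    return copies


def _flank_residues(
    mode: str, enzymes: Sequence[EnzymeSpec], motif: str
) -> tuple[str, str | None]:
    """(residue before the motif, residue after or None to keep the base)."""
    p1_allow: set[str] = set()
    p1p_deny: set[str] = set()
    for enz in enzymes:
        for rule in enz.rules:
            c = rule.window.get("P1")
            if c is not None and c.kind == "allow":
                p1_allow |= c.residues
            cp = rule.window.get("P1'")
            if cp is not None and cp.kind == "deny":
                p1p_deny |= cp.residues
    if mode == "inert":
        candidates = sorted(AMINO_ACIDS - p1_allow)
        if not candidates:
            raise ValueError("no inert flank residue exists for this enzyme set")
        pick = "Q" if "Q" in candidates else candidates[0]
        return pick, pick
    # cuttable: preceding residue must trigger a cut; boundary cut after the
    # motif needs the motif's own last residue to be cleavable.
    if motif[-1] not in p1_allow:
        raise ValueError(
            f"motif {motif!r} cannot get a cuttable C-terminal boundary: its last "
            f"residue is outside every P1 set of the selected enzymes"
        )
    before = sorted(p1_allow)[0]
    after = sorted(AMINO_ACIDS - p1p_deny - p1_allow)
    return before, (after[0] if after else None)


def plant_motifs(
    base: ProteinRecord,
    spec: SyntheticSpec,
    ruleset: Mapping[str, EnzymeSpec] | None = None,
    enzyme_sets: Sequence[Sequence[str]] = DEFAULT_ENZYME_SETS,
) -> GroundTruth:
    """Plant motif copies into ``base`` and return brute-force expectations.

    Copies replace triplet-aligned segments at seeded-random non-overlapping
    positions. In ``cuttable`` mode the flanks are engineered for the *first*
    enzyme set, and release of every copy under that set is verified with the
    naive oracle (a motif whose interior is itself cut raises ``ValueError``).
    """
    ruleset = ruleset if ruleset is not None else default_ruleset()
    enzyme_sets = tuple(tuple(s) for s in enzyme_sets)
    if not enzyme_sets:
        raise ValueError("at least one enzyme set is required")
    resolved = {s: resolve_enzymes(s, ruleset) for s in enzyme_sets}
    first_set = resolved[enzyme_sets[0]]

    rng = random.Random(f"colpep-plant-{spec.seed}")
    seq = list(base.sequence)
    n = len(seq)
    occupied: set[int] = set()
    planted: dict[str, list[int]] = {}

    for motif, copies in sorted(_grouped_motifs(spec).items()):
        length = len(motif)
        before, after = _flank_residues(spec.flank_mode, first_set, motif)
        for _ in range(copies):
            placed = False
            for _attempt in range(_MAX_PLANT_RETRIES):
                start = 3 * rng.randrange(1, max(2, (n - length - 1) // 3))
                if start + length >= n:
                    continue
                touched = range(start - 1, start + length + 1)
                if occupied.intersection(touched):
                    continue
                seq[start - 1] = before
                seq[start : start + length] = list(motif)
                if after is not None and spec.flank_mode == "cuttable":
                    seq[start + length] = after
                elif spec.flank_mode == "inert":
                    seq[start + length] = after  # type: ignore[assignment]
                occupied.update(touched)
                planted.setdefault(motif, []).append(start)
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place copy of {motif!r} after {_MAX_PLANT_RETRIES} "
                    f"seeded attempts (sequence too short or too crowded)"
                )

    sequence = "".join(seq)
    if spec.flank_mode == "cuttable":
        frags = oracle_fragments(sequence, oracle_cut_sites(sequence, first_set))
        for motif, starts in planted.items():
            if frags.count(motif) < len(starts):
                raise ValueError(
                    f"cuttable planting failed for {motif!r}: the selected enzymes "
                    f"cut inside the motif or a boundary constraint is unsatisfiable"
                )

    protein = ProteinRecord(id=base.id, sequence=sequence, organism=base.organism)
    db = make_synthetic_db(spec)

    expected_A = {
        code: Fraction(
            sum(oracle_count(sequence, p) for p in sorted(db.peptides_for_activity(code))),
            n,
        )
        for code in db.activity_codes()
    }
    expected_AE: dict[tuple[str, tuple[str, ...]], Fraction] = {}
    expected_DHt: dict[tuple[str, ...], Fraction] = {}
    for names, enzymes in resolved.items():
        sites = oracle_cut_sites(sequence, enzymes)
        frags = oracle_fragments(sequence, sites)
        expected_DHt[names] = (
            Fraction(0) if n < 2 else Fraction(100 * len(sites), n - 1)
        )
        for code in db.activity_codes():
            peps = db.peptides_for_activity(code)
            expected_AE[(code, names)] = Fraction(
                sum(1 for f in frags if f in peps), n
            )

    return GroundTruth(
        protein=protein,
        planted_positions={m: tuple(v) for m, v in planted.items()},
        expected_A=expected_A,
        expected_AE=expected_AE,
        expected_DHt=expected_DHt,
    )


def write_fixture(gt: GroundTruth, spec: SyntheticSpec, out_dir: str | Path) -> None:
    """Emit FASTA + activity TSV + ground-truth JSON so fixtures are inspectable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([gt.protein], out / "protein.fasta")
    export_activity_table(make_synthetic_db(spec), out / "activity_table.tsv")
    doc = {
        "protein_id": gt.protein.id,
        "n_residues": gt.protein.n_residues,
        "planted_positions": {m: list(v) for m, v in gt.planted_positions.items()},
        "expected_A": {c: [v.numerator, v.denominator] for c, v in gt.expected_A.items()},
        "expected_AE": {
            f"{code}|{'+'.join(names)}": [v.numerator, v.denominator]
            for (code, names), v in gt.expected_AE.items()
        },
        "expected_DHt": {
            "+".join(names): [v.numerator, v.denominator]
            for names, v in gt.expected_DHt.items()
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(doc, indent=2, sort_keys=True))
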