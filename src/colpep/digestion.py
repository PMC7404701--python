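"""Rule-based simulation of complete enzymatic hydrolysis.

The model is the one used by in silico proteolysis services: an enzyme's
specificity is a set of positional residue constraints in a P4..P4' window
around a peptide bond (Schechter–Berger nomenclature). Digestion is *complete
and simultaneous*: every bond of the intact sequence whose window satisfies
any rule of any selected enzyme is cut, so multi-enzyme action is the union
of the single-enzyme cut-site sets. No kinetics, partial digestion or
missed-cleavage enumeration is modelled.

The theoretical degree of hydrolysis is

    DH_t = 100 * (number of bonds cut) / (N - 1)

for a chain of N residues (N - 1 peptide bonds).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .sequence_io import AMINO_ACIDS, ProteinRecord

#: Relative window positions and their offsets from the P1 residue index.
#: Bond i joins residues i and i+1 (0-based), so P1 -> i, P1' -> i+1.
WINDOW_OFFSETS: Mapping[str, int] = {
    "P4": -3,
    "P3": -2,
    "P2": -1,
    "P1": 0,
    "P1'": 1,
    "P2'": 2,
    "P3'": 3,
    "P4'": 4,
}


@dataclass(frozen=True)
class Constraint:
    """An ``allow`` (residue must be in the set) or ``deny`` constraint."""

    kind: str  # "allow" | "deny"
    residues: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in ("allow", "deny"):
            raise ValueError(f"constraint kind must be allow/deny, got {self.kind!r}")
        if not self.residues:
            raise ValueError("constraint residue set must be non-empty")
        bad = self.residues - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-standard residue(s) in constraint: {sorted(bad)}")


@dataclass(frozen=True)
class CleavageRule:
    """Positional constraints defining one susceptible-bond pattern.

    At minimum P1 must be constrained. A rule fires on bond i iff every
    constrained position, mapped onto the intact sequence, is satisfied;
    positions falling off the sequence ends fail allow-constraints and
    satisfy deny-constraints (a bond near a terminus lacks the required
    context residue).
    """

    window: Mapping[str, Constraint]

    def __post_init__(self) -> None:
        unknown = set(self.window) - set(WINDOW_OFFSETS)
        if unknown:
            raise ValueError(f"unknown window position(s) {sorted(unknown)}")
        if "P1" not in self.window:
            raise ValueError("a cleavage rule must constrain P1")
        object.__setattr__(self, "window", dict(self.window))

    def fires(self, sequence: str, bond: int) -> bool:
        """Whether this rule cuts bond ``bond`` of ``sequence`` (0-based)."""
        n = len(sequence)
        for pos, constraint in self.window.items():
            j = bond + WINDOW_OFFSETS[pos]
            if j < 0 or j >= n:
                if constraint.kind == "allow":
                    return False
                continue  # deny is satisfied off the ends
            residue = sequence[j]
            if constraint.kind == "allow":
                if residue not in constraint.residues:
                    return False
            else:
                if residue in constraint.residues:
                    return False
        return True


@dataclass(frozen=True)
class EnzymeSpec:
    """A named enzyme; it cuts a bond if ANY of its rules fires."""

    name: str
    ec_number: str
    rules: tuple[CleavageRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError(f"enzyme {self.name!r} has an empty rule list")

    def cuts(self, sequence: str, bond: int) -> bool:
        return any(rule.fires(sequence, bond) for rule in self.rules)


@dataclass(frozen=True)
class DigestResult:
    """Cut sites, ordered fragments and DH_t for one protein × enzyme-set run.

    Fragments partition the protein: their concatenation reproduces the
    sequence and ``len(fragments) == len(cut_sites) + 1``. ``dh_t`` is kept as
    an exact rational (percentage); reports print it to two decimals.
    """

    protein_id: str
    enzymes: tuple[str, ...]
    cut_sites: tuple[int, ...]
    fragments: tuple[tuple[str, int, int], ...]  # (sequence, start, end) 0-based half-open
    dh_t: Fraction
    n_bonds: int


def _parse_constraint(spec: Mapping) -> Constraint:
    if not isinstance(spec, Mapping) or len(spec) != 1:
        raise ValueError(f"constraint must be a single allow/deny mapping, got {spec!r}")
    (kind, residues), = spec.items()
    if isinstance(residues, str):
        residues = frozenset(residues)
    else:
        residues = frozenset(residues or ())
    return Constraint(kind=kind, residues=residues)


def parse_ruleset(path: str | Path) -> dict[str, EnzymeSpec]:
    """Parse a YAML enzyme-specificity ruleset into named :class:`EnzymeSpec` s.

    Schema: top-level ``enzymes`` list; each entry has ``name``, ``ec`` and a
    ``rules`` list of position→constraint mappings (see the bundled
    ``biopep_2020.yaml``). Schema violations name the enzyme and rule index.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "enzymes" not in doc:
        raise ValueError(f"{path}: ruleset file must contain an 'enzymes' list")
    specs: dict[str, EnzymeSpec] = {}
    for entry in doc["enzymes"]:
        name = entry.get("name")
        if not name:
            raise ValueError(f"{path}: enzyme entry without a name")
        if name in specs:
            raise ValueError(f"{path}: duplicate enzyme name {name!r}")
        rules = []
        for idx, rule_spec in enumerate(entry.get("rules") or []):
            try:
                window = {pos: _parse_constraint(c) for pos, c in rule_spec.items()}
                rules.append(CleavageRule(window=window))
            except ValueError as exc:
                raise ValueError(f"{path}: enzyme {name!r}, rule {idx}: {exc}") from exc
        try:
            specs[name] = EnzymeSpec(name=name, ec_number=str(entry.get("ec", "")), rules=tuple(rules))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return specs


def default_ruleset() -> dict[str, EnzymeSpec]:
    """The bundled ``biopep_2020`` ruleset (six enzymes; see the YAML header)."""
    ref = resources.files("colpep.data").joinpath("biopep_2020.yaml")
    with resources.as_file(ref) as path:
        return parse_ruleset(path)


def find_cut_sites(protein: ProteinRecord, enzymes: Sequence[EnzymeSpec]) -> tuple[int, ...]:
    """All susceptible bond indices (0-based, sorted) on the intact sequence.

    Multi-enzyme action is the union of the per-enzyme site sets; the result
    is independent of enzyme order.
    """
    if not enzymes:
        raise ValueError("at least one enzyme is required")
    seq = protein.sequence
    sites = [
        i for i in range(len(seq) - 1) if any(enz.cuts(seq, i) for enz in enzymes)
    ]
    return tuple(sites)


def digest(protein: ProteinRecord, enzymes: Sequence[EnzymeSpec]) -> DigestResult:
    """Complete digestion: fragments are maximal runs between consecutive cuts."""
    seq = protein.sequence
    sites = find_cut_sites(protein, enzymes)
    n = len(seq)
    bounds = [0] + [i + 1 for i in sites] + [n]
    fragments = tuple(
        (seq[a:b], a, b) for a, b in zip(bounds[:-1], bounds[1:])
    )
    n_bonds = n - 1
    dh_t = Fraction(0) if n_bonds == 0 else Fraction(100 * len(sites), n_bonds)
    return DigestResult(
        protein_id=protein.id,
        enzymes=tuple(e.name for e in enzymes),
        cut_sites=sites,
        fragments=fragments,
        dh_t=dh_t,
        n_bonds=n_bonds,
    )


def theoretical_degree_of_hydrolysis(result: DigestResult) -> Fraction:
    """DH_t as an exact percentage: 100 × |cut sites| / (N − 1)."""
    return result.dh_t


def resolve_enzymes(
    names: Iterable[str], ruleset: Mapping[str, EnzymeSpec]
) -> list[EnzymeSpec]:
    """Map enzyme names to specs, raising on any unknown name."""
    out = []
    for name in names:
        if name not in ruleset:
            raise KeyError(
                f"unknown enzyme {name!r}; ruleset provides {sorted(ruleset)}"
            )
        out.append(ruleset[name])
    return out
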