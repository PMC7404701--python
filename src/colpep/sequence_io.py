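"""Protein sequence I/O: FASTA reading/writing, validation, mature-chain trimming.

Sequences are plain chains over the 20 standard amino acids. Post-translationally
modified residues (notably the hydroxyproline abundant in collagen) are not
representable; database entries carrying non-standard letters are either rejected
(``strict``) or stripped (``drop_unknown``).

Coordinates in the public API are 1-based inclusive, following the UniProt
feature convention; fragment coordinates elsewhere in the package are 0-based
half-open.
"""

from __future__ import annotations

import json
import logging
import re
import urllib.request
from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("colpep")

#: The 20-letter standard amino-acid alphabet.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

_CANONICAL_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWY]+$")
_STRIP_RE = re.compile(r"[\s\-\.\*]+")

UNIPROT_REST = "https://rest.uniprot.org/uniprotkb"

CanonPolicy = Literal["strict", "drop_unknown"]


@dataclass(frozen=True)
class ProteinRecord:
    """An identified, validated mature amino-acid chain.

    ``n_residues`` (the chain length N) is the denominator of the occurrence
    and release frequencies computed downstream.
    """

    id: str
    sequence: str
    organism: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein record requires a non-empty id")
        if not _CANONICAL_RE.match(self.sequence):
            raise ValueError(
                f"record {self.id!r}: sequence must be a non-empty string over "
                f"the 20-letter amino-acid alphabet; call canonicalize_sequence first"
            )

    @property
    def n_residues(self) -> int:
        return len(self.sequence)


def canonicalize_sequence(raw: str, policy: CanonPolicy = "strict") -> str:
    """Uppercase ``raw``, remove whitespace/gap characters, validate the alphabet.

    Under ``strict`` any residue outside the 20-letter alphabet (B, J, O, U, X,
    Z, ...) raises ``ValueError`` naming its 1-based position. Under
    ``drop_unknown`` such residues are removed and a warning logs the positions.
    """
    if policy not in ("strict", "drop_unknown"):
        raise ValueError(f"unknown canonicalization policy {policy!r}")
    cleaned = _STRIP_RE.sub("", raw).upper()
    if not cleaned:
        raise ValueError("sequence is empty after whitespace removal")
    bad = [(i + 1, c) for i, c in enumerate(cleaned) if c not in AMINO_ACIDS]
    if not bad:
        return cleaned
    if policy == "strict":
        pos, char = bad[0]
        raise ValueError(f"non-standard residue {char!r} at position {pos}")
    logger.warning(
        "dropped %d non-standard residue(s) at position(s) %s",
        len(bad),
        ",".join(str(p) for p, _ in bad),
    )
    kept = "".join(c for c in cleaned if c in AMINO_ACIDS)
    if not kept:
        raise ValueError("sequence is empty after dropping non-standard residues")
    return kept


def read_fasta(path: str | Path, policy: CanonPolicy = "strict") -> list[ProteinRecord]:
    """Read a (multi-record) FASTA file into validated :class:`ProteinRecord` s.

    The header token before the first whitespace becomes the record id; file
    order is preserved. A record with an empty sequence is rejected with its
    header named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        if not raw.strip("-. *"):
            raise ValueError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(id=rec.id, sequence=canonicalize_sequence(raw, policy)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to ``path`` in FASTA format (id and sequence round-trip)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(Path(path)), "fasta")


def apply_mature_range(record: ProteinRecord, start: int, end: int) -> ProteinRecord:
    """Restrict ``record`` to 1-based inclusive positions ``start..end``.

    Used to excise the mature chain (e.g. drop a signal peptide) from a
    precursor entry. The range must come from external annotation; no signal
    peptide prediction is performed. The id is annotated with the range unless
    the range is the identity.
    """
    n = record.n_residues
    if not (1 <= start <= end <= n):
        raise ValueError(
            f"range {start}..{end} out of bounds for {record.id!r} (N={n})"
        )
    if start == 1 and end == n:
        return record
    return replace(
        record,
        id=f"{record.id}|{start}-{end}",
        sequence=record.sequence[start - 1 : end],
    )


# -- optional UniProt retrieval (network-gated convenience) --------------------


def fetch_uniprot(accession: str, timeout: float = 15.0) -> ProteinRecord:
    """Fetch one UniProtKB entry as a :class:`ProteinRecord` (requires network)."""
    url = f"{UNIPROT_REST}/{accession}.fasta"
    with urllib.request.urlopen(url, timeout=timeout) as fh:
        text = fh.read().decode()
    recs = list(SeqIO.parse(StringIO(text), "fasta"))
    if not recs:
        raise ValueError(f"UniProt returned no FASTA record for {accession!r}")
    rec = recs[0]
    organism = None
    m = re.search(r"OS=(.+?)\s+OX=", rec.description)
    if m:
        organism = m.group(1)
    return ProteinRecord(
        id=accession, sequence=canonicalize_sequence(str(rec.seq), "strict"), organism=organism
    )


def uniprot_mature_range(accession: str, timeout: float = 15.0) -> tuple[int, int]:
    """Return the 1-based range of the chain after the annotated signal peptide.

    Reads the entry's UniProt feature annotation (requires network). If no
    signal peptide is annotated, returns the full range ``(1, N)``.
    """
    url = f"{UNIPROT_REST}/{accession}.json"
    with urllib.request.urlopen(url, timeout=timeout) as fh:
        entry = json.load(fh)
    n = len(entry["sequence"]["value"])
    start = 1
    for feat in entry.get("features", []):
        if feat.get("type") == "Signal":
            end_val = feat["location"]["end"].get("value")
            if end_val:
                start = max(start, int(end_val) + 1)
    return start, n
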