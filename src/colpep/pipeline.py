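"""End-to-end orchestration: proteins × enzyme sets → reports.

One run covers, per protein: the occurrence profile (parameter A with bins),
and per enzyme set: the digest (fragments, DH_t) and the release profile
(A_E, W). Released database peptides are collected into an annotated summary
(activities, sources, IC50 metadata, optional user-supplied bioactivity
likelihood scores), and the unique released bioactive peptides optionally get
a chemistry pass (SMILES + Rule of 5). Machine-readable outputs are
deterministic: identical config + inputs give byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .activity_db import PeptideActivityDB, builtin_fixture, load_activity_table
from .chem import MAX_PEPTIDE_LENGTH, LipinskiReport, MoleculeDescriptors, compute_descriptors, rule_of_five, write_smi
from .digestion import DigestResult, EnzymeSpec, default_ruleset, digest, parse_ruleset, resolve_enzymes
from .profiling import (
    ActivityProfile,
    ReleaseProfile,
    format_frequency,
    profile_occurrence,
    profile_release,
    sort_occurrence,
    sort_release,
)
from .sequence_io import ProteinRecord, apply_mature_range, read_fasta

logger = logging.getLogger("colpep")

DEFAULT_ENZYME_SETS: tuple[tuple[str, ...], ...] = (
    ("stem_bromelain",),
    ("ficin",),
    ("papain",),
    ("pepsin",),
    ("trypsin",),
    ("chymotrypsin",),
    ("pepsin", "trypsin"),
    ("pepsin", "trypsin", "chymotrypsin"),
)

SCORE_THRESHOLD = 0.5  # user-supplied bioactivity-likelihood flag cutoff


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``proteins`` is a FASTA path or a list of records; ``db`` is a TSV path,
    a loaded database, or ``"fixture"`` for the bundled one; ``ruleset`` is a
    YAML path, a parsed mapping, or ``"biopep_2020"``. ``mature_ranges`` maps
    protein ids to 1-based inclusive (start, end) mature-chain ranges.
    ``score_table`` optionally points to a two-column TSV (peptide, score) of
    externally computed bioactivity-likelihood scores that are joined — never
    computed — into the released-peptide report.
    """

    proteins: "str | Path | Sequence[ProteinRecord]"
    enzyme_sets: Sequence[Sequence[str]] = DEFAULT_ENZYME_SETS
    db: "str | Path | PeptideActivityDB" = "fixture"
    ruleset: "str | Path | Mapping[str, EnzymeSpec]" = "biopep_2020"
    mature_ranges: Mapping[str, tuple[int, int]] | None = None
    outputs: str | Path = "colpep_out"
    format: str = "tsv"
    score_table: "str | Path | None" = None
    include_chem: bool = True

    def __post_init__(self) -> None:
        if self.format not in ("tsv", "json"):
            raise ValueError(f"format must be tsv or json, got {self.format!r}")
        if not self.enzyme_sets:
            raise ValueError("at least one enzyme set is required")


@dataclass
class RunSummary:
    """In-memory results of a run, before/after report writing."""

    proteins: list[ProteinRecord]
    occurrence: dict[str, list[ActivityProfile]]
    digests: dict[tuple[str, tuple[str, ...]], DigestResult]
    release: dict[tuple[str, tuple[str, ...]], list[ReleaseProfile]]
    descriptors: list[MoleculeDescriptors]
    lipinski: list[LipinskiReport]
    failures: list[tuple[str, str]]
    manifest: dict

    @property
    def ok(self) -> bool:
        return not self.failures


def _load_ruleset(spec) -> tuple[str, dict[str, EnzymeSpec]]:
    if isinstance(spec, Mapping):
        return "custom", dict(spec)
    if spec == "biopep_2020":
        return "biopep_2020", default_ruleset()
    return str(spec), parse_ruleset(spec)


def _load_db(spec) -> PeptideActivityDB:
    if isinstance(spec, PeptideActivityDB):
        return spec
    if spec == "fixture":
        return builtin_fixture()
    return load_activity_table(spec)


def _load_proteins(config: RunConfig) -> list[ProteinRecord]:
    if isinstance(config.proteins, (str, Path)):
        records = read_fasta(config.proteins)
    else:
        records = list(config.proteins)
    if config.mature_ranges:
        records = [
            apply_mature_range(r, *config.mature_ranges[r.id])
            if r.id in config.mature_ranges
            else r
            for r in records
        ]
    return records


def _load_scores(path) -> dict[str, float]:
    if path is None:
        return {}
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str})
    if "peptide" not in df.columns or "score" not in df.columns:
        raise ValueError(f"{path}: score table needs 'peptide' and 'score' columns")
    return dict(zip(df["peptide"], df["score"].astype(float)))


def _db_fingerprint(db: PeptideActivityDB) -> str:
    payload = "\n".join(
        f"{r.peptide}\t{r.activity_code}\t{r.ic50_value}\t{r.ic50_unit}"
        for r in sorted(db.records, key=lambda r: r.key)
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_hash(config: RunConfig) -> str:
    doc = {
        "proteins": str(config.proteins) if isinstance(config.proteins, (str, Path)) else [
            r.id for r in config.proteins
        ],
        "enzyme_sets": [list(s) for s in config.enzyme_sets],
        "db": str(config.db) if not isinstance(config.db, PeptideActivityDB) else "<in-memory>",
        "ruleset": str(config.ruleset) if not isinstance(config.ruleset, Mapping) else "<in-memory>",
        "mature_ranges": {k: list(v) for k, v in (config.mature_ranges or {}).items()},
        "format": config.format,
        "include_chem": config.include_chem,
    }
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, write: bool = True) -> RunSummary:
    """Execute the full study over every protein × enzyme set.

    Enzyme names are validated against the ruleset before any computation.
    A protein that fails is reported in ``summary.failures`` and skipped;
    the CLI maps failures to a non-zero exit status.
    """
    ruleset_name, ruleset = _load_ruleset(config.ruleset)
    enzyme_sets = [tuple(s) for s in config.enzyme_sets]
    resolved = {s: resolve_enzymes(s, ruleset) for s in enzyme_sets}  # fail fast
    db = _load_db(config.db)
    proteins = _load_proteins(config)
    scores = _load_scores(config.score_table)

    occurrence: dict[str, list[ActivityProfile]] = {}
    digests: dict[tuple[str, tuple[str, ...]], DigestResult] = {}
    release: dict[tuple[str, tuple[str, ...]], list[ReleaseProfile]] = {}
    failures: list[tuple[str, str]] = []

    for protein in proteins:
        try:
            occ = profile_occurrence(protein, db)
            occurrence[protein.id] = occ
            for names in enzyme_sets:
                result = digest(protein, resolved[names])
                digests[(protein.id, names)] = result
                release[(protein.id, names)] = profile_release(protein, result, db, occ)
            logger.info(
                "profiled %s (N=%d): %d activities, %d enzyme sets",
                protein.id, protein.n_residues, len(occ), len(enzyme_sets),
            )
        except Exception as exc:  # noqa: BLE001 - partial-failure policy
            logger.error("protein %s failed: %s", protein.id, exc)
            failures.append((protein.id, str(exc)))

    released_peptides = sorted(
        {
            frag
            for result in digests.values()
            for frag, _, _ in result.fragments
        }
        & set(db.peptides())
    )
    descriptors: list[MoleculeDescriptors] = []
    lipinski: list[LipinskiReport] = []
    if config.include_chem:
        for pep in released_peptides:
            if len(pep) <= MAX_PEPTIDE_LENGTH:
                desc = compute_descriptors(pep)
                descriptors.append(desc)
                lipinski.append(rule_of_five(desc))

    manifest = {
        "package": "colpep",
        "version": __version__,
        "config_hash": _config_hash(config),
        "ruleset": ruleset_name,
        "db_fingerprint": _db_fingerprint(db),
        "n_proteins": len(proteins),
        "n_enzyme_sets": len(enzyme_sets),
        "n_failures": len(failures),
    }
    summary = RunSummary(
        proteins=proteins,
        occurrence=occurrence,
        digests=digests,
        release=release,
        descriptors=descriptors,
        lipinski=lipinski,
        failures=failures,
        manifest=manifest,
    )
    if write:
        write_report(summary, db, scores, config.outputs, config.format)
    return summary


# -- report writing ------------------------------------------------------------


def _enzset(names: tuple[str, ...]) -> str:
    return "+".join(names)


def occurrence_frame(summary: RunSummary) -> pd.DataFrame:
    rows = []
    for protein in summary.proteins:
        for p in sort_occurrence(summary.occurrence.get(protein.id, [])):
            rows.append(
                {
                    "protein_id": p.protein_id,
                    "activity_code": p.activity_code,
                    "a_count": p.a_count,
                    "A": format_frequency(p.A) or f"{float(p.A):.3f}",
                    "bin": p.bin,
                }
            )
    return pd.DataFrame(rows, columns=["protein_id", "activity_code", "a_count", "A", "bin"])


def release_frame(summary: RunSummary) -> pd.DataFrame:
    rows = []
    for (pid, names), profiles in summary.release.items():
        for p in sort_release(profiles):
            a_e, w = format_frequency(p.A_E), format_frequency(p.W)
            if not a_e and not w:  # nothing displayable at 3 decimals
                continue
            rows.append(
                {
                    "protein_id": pid,
                    "enzymes": _enzset(names),
                    "activity_code": p.activity_code,
                    "d_count": p.d_count,
                    "A_E": a_e,
                    "W": w,
                }
            )
    return pd.DataFrame(
        rows, columns=["protein_id", "enzymes", "activity_code", "d_count", "A_E", "W"]
    )


def digest_frame(summary: RunSummary) -> pd.DataFrame:
    rows = [
        {
            "protein_id": pid,
            "enzymes": _enzset(names),
            "n_bonds": r.n_bonds,
            "n_cuts": len(r.cut_sites),
            "DH_t": f"{float(r.dh_t):.2f}",
        }
        for (pid, names), r in summary.digests.items()
    ]
    return pd.DataFrame(rows, columns=["protein_id", "enzymes", "n_bonds", "n_cuts", "DH_t"])


def fragment_frame(summary: RunSummary) -> pd.DataFrame:
    rows = [
        {
            "protein_id": pid,
            "enzymes": _enzset(names),
            "start": start,
            "end": end,
            "sequence": frag,
        }
        for (pid, names), r in summary.digests.items()
        for frag, start, end in r.fragments
    ]
    return pd.DataFrame(rows, columns=["protein_id", "enzymes", "start", "end", "sequence"])


def released_peptide_frame(
    summary: RunSummary, db: PeptideActivityDB, scores: Mapping[str, float]
) -> pd.DataFrame:
    """Annotated summary of released database peptides (activities, sources,
    IC50 metadata, optional user-supplied likelihood scores)."""
    by_pep: dict[str, dict] = {}
    for (pid, names), r in summary.digests.items():
        for frag, _, _ in r.fragments:
            recs = db.records_for_peptide(frag)
            if not recs:
                continue
            row = by_pep.setdefault(
                frag,
                {
                    "peptide": frag,
                    "activities": ";".join(sorted({x.activity_code for x in recs})),
                    "sources": set(),
                    "enzyme_sets": set(),
                    "n_released": 0,
                    "ic50": ";".join(
                        f"{x.activity_code}:{x.ic50_value}{x.ic50_unit or ''}"
                        for x in sorted(recs, key=lambda x: x.key)
                        if x.ic50_value is not None
                    ),
                },
            )
            row["sources"].add(pid)
            row["enzyme_sets"].add(_enzset(names))
            row["n_released"] += 1
    rows = []
    for pep in sorted(by_pep):
        row = by_pep[pep]
        out = {
            "peptide": pep,
            "activities": row["activities"],
            "sources": ";".join(sorted(row["sources"])),
            "enzyme_sets": ";".join(sorted(row["enzyme_sets"])),
            "n_released": row["n_released"],
            "ic50": row["ic50"],
        }
        if scores:
            score = scores.get(pep)
            out["score"] = "" if score is None else f"{score:.3f}"
            out["likely_bioactive"] = (
                "" if score is None else ("yes" if score > SCORE_THRESHOLD else "no")
            )
        rows.append(out)
    cols = ["peptide", "activities", "sources", "enzyme_sets", "n_released", "ic50"]
    if scores:
        cols += ["score", "likely_bioactive"]
    return pd.DataFrame(rows, columns=cols)


def chem_frame(summary: RunSummary) -> pd.DataFrame:
    rows = [
        {
            "peptide": d.peptide,
            "smiles_neutral": d.smiles_neutral,
            "smiles_ionized": d.smiles_ionized,
            "mw": f"{d.mw:.2f}",
            "logp": f"{d.logp:.3f}",
            "logp_method": d.logp_method,
            "hbd": d.hbd,
            "hba": d.hba,
            "rule_of_5": "+" if rep.pass_all else "-",
        }
        for d, rep in zip(summary.descriptors, summary.lipinski)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "peptide", "smiles_neutral", "smiles_ionized", "mw", "logp",
            "logp_method", "hbd", "hba", "rule_of_5",
        ],
    )


def write_report(
    summary: RunSummary,
    db: PeptideActivityDB,
    scores: Mapping[str, float],
    outputs: str | Path,
    format: str = "tsv",
) -> list[Path]:
    """Write all report files; stable column and sort order; returns paths.

    In TSV, an undefined W (A == 0) or a frequency rounding to 0.000 is a
    blank cell; in JSON it is an explicit null / full-precision number.
    """
    out = Path(outputs)
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "occurrence": occurrence_frame(summary),
        "release": release_frame(summary),
        "digest_summary": digest_frame(summary),
        "fragments": fragment_frame(summary),
        "released_peptides": released_peptide_frame(summary, db, scores),
    }
    if summary.descriptors:
        frames["chem"] = chem_frame(summary)
    written = []
    if format == "tsv":
        for name, frame in frames.items():
            path = out / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            written.append(path)
    else:
        doc = {
            "occurrence": [
                {
                    "protein_id": p.protein_id,
                    "activity_code": p.activity_code,
                    "a_count": p.a_count,
                    "A": float(p.A),
                    "bin": p.bin,
                }
                for pid in sorted(summary.occurrence)
                for p in sort_occurrence(summary.occurrence[pid])
            ],
            "release": [
                {
                    "protein_id": pid,
                    "enzymes": list(names),
                    "activity_code": p.activity_code,
                    "d_count": p.d_count,
                    "A_E": float(p.A_E),
                    "W": None if p.W is None else float(p.W),
                }
                for (pid, names), profiles in summary.release.items()
                for p in sort_release(profiles)
                if p.d_count > 0 or p.W is not None and p.W > 0
            ],
            "digests": [
                {
                    "protein_id": pid,
                    "enzymes": list(names),
                    "n_bonds": r.n_bonds,
                    "n_cuts": len(r.cut_sites),
                    "DH_t": float(r.dh_t),
                }
                for (pid, names), r in summary.digests.items()
            ],
        }
        path = out / "report.json"
        path.write_text(json.dumps(doc, indent=2, sort_keys=True))
        written.append(path)
    if summary.descriptors:
        smi_path = out / "released_peptides.smi"
        write_smi(summary.descriptors, smi_path, ionized=True)
        written.append(smi_path)
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(summary.manifest, indent=2, sort_keys=True))
    written.append(manifest_path)
    return written
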