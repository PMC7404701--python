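"""Peptide cheminformatics: SMILES construction and Lipinski Rule-of-5 screen.

Short peptides (1–10 residues) are built by condensing per-residue SMILES
templates through amide bonds. Two protonation states are produced:

* *neutral* — free amine/carboxyl termini, all side chains uncharged;
* *ionized* — the dominant species at neutral pH: N-terminal ammonium (+1),
  C-terminal carboxylate (−1), Asp/Glu side-chain carboxylates (−1), Lys
  ammonium and Arg guanidinium (+1). Histidine and cysteine are left neutral.

L-amino-acid stereocentres are encoded in the templates. Descriptors follow
medicinal-chemistry convention: average molecular weight (residue masses +
one water); hydrogen-bond donors counted as donor N/O atoms and acceptors as
N + O atoms on the *ionized* (neutral-pH) species — the species a
drug-likeness screen is applied to, under which a protonated carboxylate
stops donating while an ammonium still does; and logP from the
Wildman–Crippen atom-contribution method on the neutral form (logP is
defined for the neutral species).
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pyteomics_mass
from rdkit import Chem
from rdkit.Chem import Crippen, Lipinski

from .sequence_io import AMINO_ACIDS

MAX_PEPTIDE_LENGTH = 10
WATER_MASS = 18.0153
LOGP_METHOD = "Wildman-Crippen"

# Side-chain SMILES attached to the alpha carbon (None for glycine).
_SIDE_CHAINS: dict[str, str | None] = {
    "A": "C",
    "R": "CCCNC(N)=N",
    "N": "CC(N)=O",
    "D": "CC(O)=O",
    "C": "CS",
    "E": "CCC(O)=O",
    "Q": "CCC(N)=O",
    "G": None,
    "H": "Cc1c[nH]cn1",
    "I": "[C@@H](C)CC",
    "L": "CC(C)C",
    "K": "CCCCN",
    "M": "CCSC",
    "F": "Cc1ccccc1",
    "S": "CO",
    "T": "[C@H](O)C",
    "W": "Cc1c[nH]c2ccccc12",
    "Y": "Cc1ccc(O)cc1",
    "V": "C(C)C",
}

# Charged side-chain variants introduced in the ionized (neutral-pH) form.
_SIDE_CHAINS_IONIZED: dict[str, str] = {
    "R": "CCCNC(N)=[NH2+]",
    "D": "CC([O-])=O",
    "E": "CCC([O-])=O",
    "K": "CCCC[NH3+]",
}


def _residue_smiles(aa: str, ionized: bool, n_terminal: bool) -> str:
    """SMILES of one residue, opening with its backbone N and ending at C(=O)."""
    if aa == "P":
        # Prolyl nitrogen is part of the pyrrolidine ring; a ring-opening
        # digit keeps the template concatenable.
        nterm = "[NH2+]9" if (ionized and n_terminal) else "N9"
        return f"{nterm}CCC[C@H]9C(=O)"
    nterm = "[NH3+]" if (ionized and n_terminal) else "N"
    side = _SIDE_CHAINS_IONIZED.get(aa) if ionized else None
    if side is None:
        side = _SIDE_CHAINS[aa]
    if side is None:  # glycine: no stereocentre
        return f"{nterm}CC(=O)"
    return f"{nterm}[C@@H]({side})C(=O)"


def peptide_to_smiles(peptide: str, ionized: bool = False) -> str:
    """Condense per-residue templates into a peptide SMILES string.

    ``peptide`` must be canonical and 1–10 residues long. The output parses
    in RDKit; equivalence between builds is defined up to RDKit
    canonicalization, not byte identity.
    """
    _check_peptide(peptide)
    parts = [
        _residue_smiles(aa, ionized, n_terminal=(i == 0))
        for i, aa in enumerate(peptide)
    ]
    smiles = "".join(parts) + ("[O-]" if ionized else "O")
    if Chem.MolFromSmiles(smiles) is None:  # pragma: no cover - template guard
        raise RuntimeError(f"internal error: template SMILES failed to parse: {smiles}")
    return smiles


def _check_peptide(peptide: str) -> None:
    if not peptide or len(peptide) > MAX_PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide length must be 1..{MAX_PEPTIDE_LENGTH}, got {len(peptide)}"
        )
    bad = set(peptide) - AMINO_ACIDS
    if bad:
        raise ValueError(f"unsupported residue(s) {sorted(bad)} in {peptide!r}")


def canonical_smiles(smiles: str) -> str:
    """RDKit canonical (isomeric) form of ``smiles``."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES failed to parse: {smiles!r}")
    return Chem.MolToSmiles(mol)


def formal_charge(smiles: str) -> int:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"SMILES failed to parse: {smiles!r}")
    return Chem.GetFormalCharge(mol)


@dataclass(frozen=True)
class MoleculeDescriptors:
    """Rule-of-5 descriptors of a peptide."""

    peptide: str
    smiles_neutral: str
    smiles_ionized: str
    mw: float  # average molecular weight, Da
    hbd: int  # donor N/O atoms on the ionized (neutral-pH) species
    hba: int  # N + O atoms (identical heavy-atom graph in both forms)
    logp: float
    logp_method: str = LOGP_METHOD


@dataclass(frozen=True)
class LipinskiReport:
    """Pass/fail flags of the four Rule-of-5 criteria."""

    peptide: str
    pass_mw: bool
    pass_logp: bool
    pass_hbd: bool
    pass_hba: bool

    @property
    def pass_all(self) -> bool:
        return self.pass_mw and self.pass_logp and self.pass_hbd and self.pass_hba


def average_mass(peptide: str) -> float:
    """Average molecular mass: standard residue masses plus one water."""
    _check_peptide(peptide)
    return float(_pyteomics_mass.calculate_mass(sequence=peptide, average=True))


def compute_descriptors(peptide: str) -> MoleculeDescriptors:
    """Build both SMILES forms and the Rule-of-5 descriptor set."""
    smiles_neutral = peptide_to_smiles(peptide, ionized=False)
    smiles_ionized = peptide_to_smiles(peptide, ionized=True)
    mol_neutral = Chem.MolFromSmiles(smiles_neutral)
    mol_ionized = Chem.MolFromSmiles(smiles_ionized)
    return MoleculeDescriptors(
        peptide=peptide,
        smiles_neutral=smiles_neutral,
        smiles_ionized=smiles_ionized,
        mw=average_mass(peptide),
        hbd=Lipinski.NumHDonors(mol_ionized),
        hba=Lipinski.NOCount(mol_ionized),
        logp=Crippen.MolLogP(mol_neutral),
    )


def rule_of_five(desc: MoleculeDescriptors) -> LipinskiReport:
    """Lipinski screen: MW ≤ 500 Da, logP ≤ 5, HBD ≤ 5, HBA ≤ 10."""
    return LipinskiReport(
        peptide=desc.peptide,
        pass_mw=desc.mw <= 500.0,
        pass_logp=desc.logp <= 5.0,
        pass_hbd=desc.hbd <= 5,
        pass_hba=desc.hba <= 10,
    )


def write_smi(descriptors, path, ionized: bool = True) -> None:
    """Write a .smi file (SMILES, whitespace, identifier; one per line)."""
    with open(path, "w") as fh:
        for d in descriptors:
            smiles = d.smiles_ionized if ionized else d.smiles_neutral
            fh.write(f"{smiles} {d.peptide}\n")
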