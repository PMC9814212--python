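"""Shared RDKit helpers: lenient parsing and canonical graph keys."""

from __future__ import annotations

from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

RDLogger.DisableLog("rdApp.*")


def mol_from_smiles(smiles: str, lenient: bool = True) -> Chem.Mol | None:
    """Parse SMILES; on sanitization failure optionally retry after
    structure normalization (rewrites hypervalent nitro/N-oxide/azide
    depictions to charge-separated forms)."""
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles)
    if mol is not None or not lenient:
        return mol
    raw = Chem.MolFromSmiles(smiles, sanitize=False)
    if raw is None:
        return None
    try:
        fixed = rdMolStandardize.Normalize(raw)
        Chem.SanitizeMol(fixed)
    except Exception:
        return None
    return fixed


def canonical_smiles(mol_or_smiles, isomeric: bool = True) -> str | None:
    """Canonical SMILES of a molecule or SMILES string; None if unparseable."""
    mol = _as_mol(mol_or_smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol, isomericSmiles=isomeric)


def graph_key(mol_or_smiles) -> str | None:
    """Canonical key of the heavy-atom graph, ignoring stereochemistry.

    Two SMILES dialects of one molecule (original / canonical / explicit-H)
    map to the same key, which is the identity used for variant
    deduplication and duplicate detection.
    """
    return canonical_smiles(mol_or_smiles, isomeric=False)


def _as_mol(mol_or_smiles) -> Chem.Mol | None:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    return mol_from_smiles(mol_or_smiles)
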