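"""Molecule graph -> per-atom feature matrix + neighbor lists.

The feature layout (NUM_ATOM_FEATURES = 27 columns) is a fixed contract with
the network; trained models are not portable across layout changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from taulogp.chem import mol_from_smiles

logger = logging.getLogger(__name__)

ELEMENTS = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I")  # + "other" bucket
MAX_DEGREE = 5
MAX_H = 4

#: layout: element one-hot (10) | degree one-hot 0-5 (6) | H-count one-hot
#: 0-4 (5) | formal charge (1) | aromatic (1) | in-ring (1) | hybridization
#: one-hot sp/sp2/sp3 (3)
NUM_ATOM_FEATURES = len(ELEMENTS) + 1 + (MAX_DEGREE + 1) + (MAX_H + 1) + 1 + 1 + 1 + 3
FEATURE_LAYOUT_ID = "taulogp-atomfeat-v1"


@dataclass
class GraphFeatures:
    """Featurized heavy-atom graph of one molecule."""

    node_features: np.ndarray  # (n_atoms, NUM_ATOM_FEATURES) float32
    neighbor_lists: list[np.ndarray]  # per-atom heavy neighbor indices
    degree_histogram: np.ndarray  # counts per degree 0..MAX_DEGREE

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]


def _hybridization_index(atom: Chem.Atom) -> int:
    """0 = sp, 1 = sp2, 2 = sp3; derived from connectivity, everything
    exotic clamps to sp3, aromatic atoms are sp2."""
    if atom.GetIsAromatic():
        return 1
    hyb = atom.GetHybridization()
    if hyb == Chem.HybridizationType.SP:
        return 0
    if hyb == Chem.HybridizationType.SP2:
        return 1
    return 2


def featurize(mol_or_smiles) -> GraphFeatures:
    """Fixed-width per-atom features; hydrogens are implicit (no H nodes)."""
    mol = mol_or_smiles if isinstance(mol_or_smiles, Chem.Mol) else mol_from_smiles(mol_or_smiles)
    if mol is None:
        raise ValueError(f"featurize: unparseable molecule {mol_or_smiles!r}")
    n = mol.GetNumAtoms()
    feats = np.zeros((n, NUM_ATOM_FEATURES), dtype=np.float32)
    neighbor_lists: list[np.ndarray] = []
    degree_hist = np.zeros(MAX_DEGREE + 1, dtype=np.int64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        col = 0
        symbol = atom.GetSymbol()
        if symbol in ELEMENTS:
            feats[i, col + ELEMENTS.index(symbol)] = 1.0
        else:
            logger.warning("featurize: element %s outside alphabet, using 'other'", symbol)
            feats[i, col + len(ELEMENTS)] = 1.0
        col += len(ELEMENTS) + 1
        degree = atom.GetDegree()
        if degree > MAX_DEGREE:
            logger.warning("featurize: degree %d clamped to %d", degree, MAX_DEGREE)
            degree = MAX_DEGREE
        feats[i, col + degree] = 1.0
        col += MAX_DEGREE + 1
        feats[i, col + min(atom.GetTotalNumHs(), MAX_H)] = 1.0
        col += MAX_H + 1
        feats[i, col] = float(atom.GetFormalCharge())
        col += 1
        feats[i, col] = 1.0 if atom.GetIsAromatic() else 0.0
        col += 1
        feats[i, col] = 1.0 if atom.IsInRing() else 0.0
        col += 1
        feats[i, col + _hybridization_index(atom)] = 1.0
        degree_hist[degree] += 1
        neighbor_lists.append(np.array(sorted(nb.GetIdx() for nb in atom.GetNeighbors()), dtype=np.int64))
    return GraphFeatures(node_features=feats, neighbor_lists=neighbor_lists, degree_histogram=degree_hist)


def count_nha(mol_or_smiles) -> int:
    """Number of non-hydrogen (heavy) atoms."""
    mol = mol_or_smiles if isinstance(mol_or_smiles, Chem.Mol) else mol_from_smiles(mol_or_smiles)
    if mol is None:
        raise ValueError(f"count_nha: unparseable molecule {mol_or_smiles!r}")
    return mol.GetNumHeavyAtoms()


def dump_features(gf: GraphFeatures) -> str:
    """Human-readable debug dump: one whitespace-separated row per atom."""
    lines = [f"# {gf.n_atoms} atoms x {NUM_ATOM_FEATURES} features ({FEATURE_LAYOUT_ID})"]
    for i in range(gf.n_atoms):
        row = " ".join(f"{v:g}" for v in gf.node_features[i])
        nbrs = ",".join(str(j) for j in gf.neighbor_lists[i])
        lines.append(f"{i}\t[{nbrs}]\t{row}")
    return "\n".join(lines)
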