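"""Rule-based tautomer enumeration.

A single proton-shift engine drives all rules: a hydrogen migrates along an
alternating single/double bond path whose bond orders are then flipped.
Three-atom paths implement the classic 1,3 shifts (keto-enol,
amide-imidic acid / lactam-lactim, imine-enamine, and 1,3 shifts between
ring nitrogens); five/seven-atom paths implement the nitroso-oxime shift
extended through an aromatic ring (ortho/para nitrosophenol vs quinone
monoxime).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from rdkit import Chem
from rdkit.Chem.rdMolDescriptors import CalcMolFormula

from taulogp.chem import canonical_smiles, graph_key, mol_from_smiles

logger = logging.getLogger(__name__)

#: allowed (donor, pivot, acceptor) element triples for 1,3 shifts, with the
#: rule name each one realizes. Both directions of every rule are listed so
#: that enumeration is closed under reversal.
_TRIADS: dict[tuple[str, str, str], str] = {
    ("C", "C", "O"): "keto_enol",
    ("O", "C", "C"): "keto_enol",
    ("N", "C", "O"): "amide_imidic",
    ("O", "C", "N"): "amide_imidic",
    ("C", "C", "N"): "imine_enamine",
    ("N", "C", "C"): "imine_enamine",
    ("N", "C", "N"): "aza_13_shift",
}

_S = Chem.BondType.SINGLE
_D = Chem.BondType.DOUBLE


@dataclass
class TautomerSet:
    """Closure of a molecule under the shift rules, keyed by canonical form."""

    parent: str
    members: list[str]
    rule_trace: dict[str, list[str]] = field(default_factory=dict)
    truncated: bool = False

    def __contains__(self, smiles: str) -> bool:
        return canonical_smiles(smiles) in self.members


def _prepared(mol: Chem.Mol) -> Chem.RWMol:
    """Kekulized editable copy with hydrogen counts frozen."""
    m = Chem.RWMol(mol)
    Chem.Kekulize(m, clearAromaticFlags=True)
    for atom in m.GetAtoms():
        atom.SetNumExplicitHs(atom.GetTotalNumHs())
        atom.SetNoImplicit(True)
    return m


def _n_aromatic_rings(mol: Chem.Mol) -> int:
    ri = mol.GetRingInfo()
    return sum(
        1
        for ring in ri.BondRings()
        if all(mol.GetBondWithIdx(b).GetIsAromatic() for b in ring)
    )


def _n_cumulated(mol: Chem.Mol) -> int:
    """Number of atoms carrying two or more double bonds (allene centers)."""
    count = 0
    for atom in mol.GetAtoms():
        doubles = sum(1 for b in atom.GetBonds() if b.GetBondType() == _D)
        if doubles >= 2:
            count += 1
    return count


def _apply_shift(kek: Chem.RWMol, path: list[int]) -> Chem.Mol | None:
    """Move one H from path[0] to path[-1] and flip bond orders along the
    path; returns the sanitized product or None if illegal."""
    m = Chem.RWMol(kek)
    bonds = [m.GetBondBetweenAtoms(path[i], path[i + 1]) for i in range(len(path) - 1)]
    pattern = [_S, _D]
    if any(b is None or b.GetBondType() != pattern[i % 2] for i, b in enumerate(bonds)):
        return None
    donor = m.GetAtomWithIdx(path[0])
    acceptor = m.GetAtomWithIdx(path[-1])
    if donor.GetNumExplicitHs() < 1:
        return None
    donor.SetNumExplicitHs(donor.GetNumExplicitHs() - 1)
    acceptor.SetNumExplicitHs(acceptor.GetNumExplicitHs() + 1)
    for i, bond in enumerate(bonds):
        bond.SetBondType(pattern[(i + 1) % 2])
    product = m.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception:
        return None
    # valence-legal but chemically absurd cumulenes (C=C=C) can appear when
    # shifting within quinoid systems; reject any newly created one
    if _n_cumulated(product) > _n_cumulated(kek):
        return None
    # a shift can destroy stereocenters; drop stereo on the product rather
    # than emit ill-defined descriptors
    Chem.AssignStereochemistry(product, cleanIt=True, force=True)
    return product


def _triad_moves(kek: Chem.RWMol, n_arom_parent: int):
    """All legal 1,3-shift products. Shifts that would destroy an aromatic
    ring are rejected (quinoid products are reachable only through the
    ring-extended nitroso-oxime rule)."""
    for donor in kek.GetAtoms():
        if donor.GetNumExplicitHs() < 1:
            continue
        x = donor.GetSymbol()
        for pivot in donor.GetNeighbors():
            bond_xy = kek.GetBondBetweenAtoms(donor.GetIdx(), pivot.GetIdx())
            if bond_xy.GetBondType() != _S:
                continue
            for acceptor in pivot.GetNeighbors():
                if acceptor.GetIdx() == donor.GetIdx():
                    continue
                triad = (x, pivot.GetSymbol(), acceptor.GetSymbol())
                rule = _TRIADS.get(triad)
                if rule is None:
                    continue
                product = _apply_shift(kek, [donor.GetIdx(), pivot.GetIdx(), acceptor.GetIdx()])
                if product is None:
                    continue
                if _n_aromatic_rings(product) < n_arom_parent:
                    continue
                if rule == "amide_imidic" and pivot.IsInRing():
                    rule = "lactam_lactim"
                yield product, rule


def _ring_extended_moves(kek: Chem.RWMol):
    """Nitroso-oxime shifts through a ring: H migrates along a 5- or 7-atom
    alternating path between two oxygens with a nitrogen at one end."""
    for donor in kek.GetAtoms():
        if donor.GetSymbol() != "O" or donor.GetNumExplicitHs() < 1:
            continue
        # DFS over simple alternating paths starting with a single bond
        stack = [[donor.GetIdx()]]
        while stack:
            path = stack.pop()
            want = [_S, _D][(len(path) - 1) % 2]
            last = kek.GetAtomWithIdx(path[-1])
            for nbr in last.GetNeighbors():
                j = nbr.GetIdx()
                if j in path:
                    continue
                bond = kek.GetBondBetweenAtoms(path[-1], j)
                if bond.GetBondType() != want:
                    continue
                new_path = path + [j]
                if len(new_path) in (5, 7) and nbr.GetSymbol() == "O" and want is _D:
                    if _valid_nitroso_path(kek, new_path):
                        product = _apply_shift(kek, new_path)
                        if product is not None:
                            yield product, "nitroso_oxime_ring"
                if len(new_path) < 7:
                    stack.append(new_path)


def _valid_nitroso_path(kek: Chem.RWMol, path: list[int]) -> bool:
    symbols = [kek.GetAtomWithIdx(i).GetSymbol() for i in path]
    if symbols[0] != "O" or symbols[-1] != "O":
        return False
    interior = symbols[1:-1]
    # exactly one nitrogen, adjacent to one of the two oxygens
    if interior.count("N") != 1 or not (symbols[1] == "N" or symbols[-2] == "N"):
        return False
    if any(s not in ("C", "N") for s in interior):
        return False
    # the carbon backbone must run through a ring
    return all(kek.GetAtomWithIdx(i).IsInRing() for i, s in zip(path, symbols) if s == "C")


def _neighbors(smiles: str) -> list[tuple[str, str]]:
    """Deterministic (canonical product SMILES, rule) list for one member."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        return []
    kek = _prepared(mol)
    parent_formula = CalcMolFormula(mol)
    n_arom = _n_aromatic_rings(mol)
    out: dict[str, str] = {}
    for product, rule in list(_triad_moves(kek, n_arom)) + list(_ring_extended_moves(kek)):
        if CalcMolFormula(product) != parent_formula:  # pragma: no cover - engine guard
            continue
        key = Chem.MolToSmiles(product)
        out.setdefault(key, rule)
    return sorted(out.items())


def enumerate_tautomers(mol_or_smiles, max_members: int = 32, max_depth: int = 4) -> TautomerSet:
    """Breadth-first closure of a molecule under the shift rules.

    Deduplicated by canonical SMILES; member order is the canonical-string
    sort, so two calls on the same input are identical. Hitting either cap
    flags the set as truncated instead of failing.
    """
    if isinstance(mol_or_smiles, Chem.Mol):
        parent = Chem.MolToSmiles(mol_or_smiles)
    else:
        parent = canonical_smiles(mol_or_smiles)
    if parent is None:
        raise ValueError(f"unparseable molecule: {mol_or_smiles!r}")
    members: dict[str, list[str]] = {parent: []}
    truncated = False
    queue: list[tuple[str, int]] = [(parent, 0)]
    while queue:
        current, depth = queue.pop(0)
        if depth >= max_depth:
            continue
        for product, rule in _neighbors(current):
            if product in members:
                continue
            if len(members) >= max_members:
                truncated = True
                queue.clear()
                break
            members[product] = members[current] + [rule]
            queue.append((product, depth + 1))
    ordered = sorted(members)
    return TautomerSet(parent=parent, members=ordered, rule_trace={s: members[s] for s in ordered}, truncated=truncated)


def dedupe_variants(smiles_list: list[str]) -> list[str]:
    """One entry per distinct heavy-atom graph, first occurrence kept."""
    seen: set[str] = set()
    out: list[str] = []
    for smiles in smiles_list:
        key = graph_key(smiles)
        if key is None:
            logger.warning("dedupe_variants: skipping unparseable SMILES %r", smiles)
            continue
        if key not in seen:
            seen.add(key)
            out.append(smiles)
    return out


def same_tautomer_group(a, b, max_members: int = 32, max_depth: int = 4) -> bool:
    """True iff the enumerated tautomer sets of a and b intersect."""
    set_a = enumerate_tautomers(a, max_members=max_members, max_depth=max_depth)
    set_b = enumerate_tautomers(b, max_members=max_members, max_depth=max_depth)
    keys_a = {graph_key(s) for s in set_a.members}
    keys_b = {graph_key(s) for s in set_b.members}
    return bool(keys_a & keys_b)
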