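"""Molecular dataset I/O, structure normalization, variant tables and splits."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.MolStandardize import rdMolStandardize

from taulogp.chem import canonical_smiles, graph_key, mol_from_smiles

logger = logging.getLogger(__name__)

LOGP_SANE_RANGE = (-5.0, 12.0)


class IonClass(str, Enum):
    NEUTRAL = "neutral"
    ANION = "anion"
    CATION = "cation"
    ZWITTERION = "zwitterion"
    UNKNOWN = "unknown"


class VariantKind(str, Enum):
    ORIGINAL = "original"
    CANONICAL = "canonical"
    EXPLICIT_H = "explicit_h"
    TAUTOMER = "tautomer"


class Partition(str, Enum):
    TRAIN = "train"
    VALID = "valid"
    TEST = "test"


@dataclass
class MoleculeRecord:
    """One dataset row: identifier, structure and macro log P label."""

    id: str
    smiles: str
    logp_exp: float | None = None
    pka_acidic: list[float] | None = None
    pka_basic: list[float] | None = None
    ion_class: IonClass = IonClass.UNKNOWN

    def mol(self) -> Chem.Mol | None:
        return mol_from_smiles(self.smiles)


@dataclass
class VariantRow:
    """One augmented representation of a parent record.

    ``label`` is always the parent's macro log P: every tautomer/SMILES
    variant is trained against the experimentally observable macro value.
    """

    parent_id: str
    variant_smiles: str
    variant_kind: VariantKind
    label: float | None


@dataclass
class SplitAssignment:
    """Parent-level train/valid/test partition; variants inherit it."""

    partition: dict[str, Partition]

    def of(self, parent_id: str) -> Partition:
        return self.partition[parent_id]

    def ids(self, part: Partition | str) -> list[str]:
        part = Partition(part)
        return [pid for pid, p in self.partition.items() if p == part]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parent_id": list(self.partition), "partition": [p.value for p in self.partition.values()]}
        )


@dataclass
class LoadReport:
    n_accepted: int = 0
    n_rejected: int = 0
    reasons: list[str] = field(default_factory=list)


DEFAULT_COLUMNS: Mapping[str, str] = {
    "id": "id",
    "smiles": "smiles",
    "logp": "logp",
    "pka_acidic": "pka_acidic",
    "pka_basic": "pka_basic",
}


def _parse_pka_cell(cell) -> list[float] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    if isinstance(cell, (int, float)):
        return [float(cell)]
    text = str(cell).strip()
    if not text:
        return None
    vals = [float(tok) for tok in text.replace(",", ";").split(";") if tok.strip()]
    return vals or None


def read_dataset(
    path,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[MoleculeRecord], LoadReport]:
    """Read a delimited-text dataset into records.

    Rows with unparseable SMILES are skipped and counted in the returned
    :class:`LoadReport`; a missing file or a missing mandatory column
    (id, smiles) raises.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    for key in ("id", "smiles"):
        if colmap[key] not in df.columns:
            raise ValueError(f"mandatory column '{colmap[key]}' missing from {path}")
    has_logp = colmap["logp"] in df.columns
    has_pka = colmap["pka_acidic"] in df.columns
    has_pkb = colmap["pka_basic"] in df.columns
    has_ion = "ion_class" in df.columns

    records: list[MoleculeRecord] = []
    report = LoadReport()
    for _, row in df.iterrows():
        rid = str(row[colmap["id"]])
        smiles = row[colmap["smiles"]]
        if not isinstance(smiles, str) or mol_from_smiles(smiles) is None:
            report.n_rejected += 1
            report.reasons.append(f"{rid}: unparseable SMILES {smiles!r}")
            logger.warning("rejected row %s: unparseable SMILES %r", rid, smiles)
            continue
        logp = None
        if has_logp and not pd.isna(row[colmap["logp"]]):
            logp = float(row[colmap["logp"]])
            if not math.isfinite(logp):
                report.n_rejected += 1
                report.reasons.append(f"{rid}: non-finite log P")
                continue
            if not LOGP_SANE_RANGE[0] <= logp <= LOGP_SANE_RANGE[1]:
                logger.warning("record %s: log P %.3g outside typical range %s", rid, logp, LOGP_SANE_RANGE)
        rec = MoleculeRecord(
            id=rid,
            smiles=smiles,
            logp_exp=logp,
            pka_acidic=_parse_pka_cell(row[colmap["pka_acidic"]]) if has_pka else None,
            pka_basic=_parse_pka_cell(row[colmap["pka_basic"]]) if has_pkb else None,
            ion_class=IonClass(row["ion_class"]) if has_ion and not pd.isna(row["ion_class"]) else IonClass.UNKNOWN,
        )
        records.append(rec)
        report.n_accepted += 1
    return records, report


def write_dataset(records: Iterable[MoleculeRecord], path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "smiles": r.smiles,
                "logp": r.logp_exp,
                "pka_acidic": ";".join(f"{v:g}" for v in r.pka_acidic) if r.pka_acidic else None,
                "pka_basic": ";".join(f"{v:g}" for v in r.pka_basic) if r.pka_basic else None,
                "ion_class": r.ion_class.value,
            }
        )
    pd.DataFrame(rows, columns=["id", "smiles", "logp", "pka_acidic", "pka_basic", "ion_class"]).to_csv(
        path, index=False
    )


def read_sdf(path, logp_property: str = "logp") -> tuple[list[MoleculeRecord], LoadReport]:
    """Optional V2000 SDF reader; ``logp_property`` names the property tag."""
    records: list[MoleculeRecord] = []
    report = LoadReport()
    for i, mol in enumerate(Chem.SDMolSupplier(str(path))):
        if mol is None:
            report.n_rejected += 1
            report.reasons.append(f"entry {i}: unparseable molblock")
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"sdf-{i}"
        logp = float(mol.GetProp(logp_property)) if mol.HasProp(logp_property) else None
        records.append(MoleculeRecord(id=rid, smiles=Chem.MolToSmiles(mol), logp_exp=logp))
        report.n_accepted += 1
    return records, report


# ---------------------------------------------------------------------------
# structure normalization & salt stripping
# ---------------------------------------------------------------------------


def normalize_structure(mol: Chem.Mol) -> Chem.Mol:
    """Rewrite hypervalent/dative depictions (nitro, N-oxide, azide) to the
    charge-separated standard form; idempotent, other atoms untouched."""
    if mol is None:
        raise ValueError("normalize_structure: molecule is None")
    out = rdMolStandardize.Normalize(mol)
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - unfixable valence
        raise ValueError(f"unfixable valence violation: {exc}") from exc
    return out


#: counterion whitelist: alkali/alkaline-earth cations, halides, ammonium and
#: common small inorganic ions (canonical SMILES keys).
COUNTERION_WHITELIST = frozenset(
    [
        "[Li+]", "[Na+]", "[K+]", "[Rb+]", "[Cs+]",
        "[Mg+2]", "[Ca+2]", "[Sr+2]", "[Ba+2]", "[Zn+2]",
        "[F-]", "[Cl-]", "[Br-]", "[I-]",
        "[NH4+]", "[OH-]", "O",
        "[O-]S(=O)(=O)[O-]", "O=S(=O)([O-])O", "[O-][N+](=O)[O-]", "O=[N+]([O-])[O-]",
        "O=P([O-])([O-])[O-]", "O=C([O-])[O-]", "[O-]C(=O)[O-]",
    ]
)


@dataclass
class SaltStripResult:
    parent: Chem.Mol
    counterions: list[str]
    ambiguous: bool = False


def strip_salt(mol: Chem.Mol) -> SaltStripResult:
    """Return the largest organic fragment with whitelisted counterions
    removed; the parent is neutralized when a removed counterion balanced
    its charge. Two equal-size organic fragments → ambiguous flag."""
    frags = Chem.GetMolFrags(mol, asMols=True)
    if len(frags) == 1:
        return SaltStripResult(parent=mol, counterions=[])
    counterions: list[str] = []
    organics: list[Chem.Mol] = []
    for frag in frags:
        key = Chem.MolToSmiles(frag)
        if key in COUNTERION_WHITELIST or frag.GetNumHeavyAtoms() == 1:
            counterions.append(key)
        else:
            organics.append(frag)
    if not organics:
        # all fragments whitelisted: keep the largest as parent anyway
        organics = sorted(frags, key=lambda m: m.GetNumHeavyAtoms(), reverse=True)[:1]
        counterions = [Chem.MolToSmiles(f) for f in frags[1:]]
    sizes = sorted((f.GetNumHeavyAtoms() for f in organics), reverse=True)
    ambiguous = len(organics) > 1 and sizes[0] == sizes[1]
    if ambiguous:
        combined = organics[0]
        for other in organics[1:]:
            combined = Chem.CombineMols(combined, other)
        return SaltStripResult(parent=combined, counterions=counterions, ambiguous=True)
    parent = max(organics, key=lambda m: m.GetNumHeavyAtoms())
    removed_charge = Chem.GetFormalCharge(mol) - Chem.GetFormalCharge(parent)
    if counterions and Chem.GetFormalCharge(parent) != 0 and removed_charge != 0:
        parent = rdMolStandardize.Uncharger().uncharge(parent)
    return SaltStripResult(parent=parent, counterions=counterions)


# ---------------------------------------------------------------------------
# variant table (data augmentation)
# ---------------------------------------------------------------------------


def explicit_h_smiles(mol: Chem.Mol) -> str:
    return Chem.MolToSmiles(Chem.AddHs(mol))


def build_variant_table(
    record: MoleculeRecord,
    tautomer_set=None,
    include: Sequence[str] = ("original", "canonical", "explicit_h", "tautomer"),
) -> list[VariantRow]:
    """All representations of one parent, deduplicated by heavy-atom graph.

    Row order (and collision tie-break) is fixed: original, canonical,
    explicit-H, then tautomers in the enumerator's deterministic order.
    Every row carries the parent's macro log P label.
    """
    mol = record.mol()
    if mol is None:
        raise ValueError(f"record {record.id}: unparseable SMILES")
    candidates: list[tuple[str, VariantKind]] = []
    if "original" in include:
        candidates.append((record.smiles, VariantKind.ORIGINAL))
    if "canonical" in include:
        candidates.append((canonical_smiles(mol), VariantKind.CANONICAL))
    if "explicit_h" in include:
        candidates.append((explicit_h_smiles(mol), VariantKind.EXPLICIT_H))
    if "tautomer" in include and tautomer_set is not None:
        for taut in tautomer_set.members:
            candidates.append((taut, VariantKind.TAUTOMER))
    rows: list[VariantRow] = []
    seen: set[str] = set()
    for smiles, kind in candidates:
        key = graph_key(smiles)
        if key is None or key in seen:
            continue
        seen.add(key)
        rows.append(VariantRow(parent_id=record.id, variant_smiles=smiles, variant_kind=kind, label=record.logp_exp))
    return rows


def write_variant_table(rows: Iterable[VariantRow], path) -> None:
    pd.DataFrame(
        [
            {"parent_id": r.parent_id, "variant_smiles": r.variant_smiles,
             "variant_kind": r.variant_kind.value, "label": r.label}
            for r in rows
        ]
    ).to_csv(path, index=False)


def read_variant_table(path) -> list[VariantRow]:
    df = pd.read_csv(path)
    return [
        VariantRow(
            parent_id=str(r.parent_id),
            variant_smiles=r.variant_smiles,
            variant_kind=VariantKind(r.variant_kind),
            label=None if pd.isna(r.label) else float(r.label),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    records: Sequence[MoleculeRecord] | Sequence[str],
    test_frac: float = 0.10,
    valid_frac_of_rest: float = 0.20,
    seed: int = 0,
) -> SplitAssignment:
    """Group-aware random split at the parent level.

    Test size is round-half-up(test_frac * n); the remainder is split
    train/valid with the same rounding on the valid count. Splitting
    13,889 records at 10% therefore withholds 1,389 and leaves 12,500
    for model development. Deterministic under a fixed seed.
    """
    if not 0 < test_frac < 1 or not 0 < valid_frac_of_rest < 1:
        raise ValueError("split fractions must lie in (0, 1)")
    ids = [r.id if isinstance(r, MoleculeRecord) else str(r) for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate parent ids in split input")
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    n_test = _round_half_up(test_frac * n)
    n_valid = _round_half_up(valid_frac_of_rest * (n - n_test))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment: dict[str, Partition] = {}
    for rank, idx in enumerate(order):
        if rank < n_test:
            part = Partition.TEST
        elif rank < n_test + n_valid:
            part = Partition.VALID
        else:
            part = Partition.TRAIN
        assignment[ids[idx]] = part
    return SplitAssignment(partition=assignment)
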