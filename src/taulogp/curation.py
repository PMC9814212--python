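"""Dataset-curation computations: outlier flags, duplicate detection and
size-stratified error analysis.

Flags are advisory only — which record of a duplicate group to keep, or
whether an outlier's primary source is wrong, is a manual decision; the
tools here only narrow the candidates to a manageable number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from taulogp.chem import graph_key
from taulogp.dataset import MoleculeRecord, strip_salt
from taulogp.featurize import count_nha
from taulogp.tautomers import enumerate_tautomers

logger = logging.getLogger(__name__)


@dataclass
class CurationFlag:
    parent_id: str
    flag_kind: str  # outlier_single | outlier_ensemble | duplicate_*
    evidence: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"parent_id": self.parent_id, "flag_kind": self.flag_kind,
                "evidence": json.dumps(self.evidence, sort_keys=True)}


def flag_outliers(experimental, predicted, ids=None, threshold: float = 1.0) -> list[CurationFlag]:
    """Flag items where |experimental - predicted| is strictly greater than
    the threshold (boundary items are not flagged)."""
    experimental = np.asarray(experimental, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if experimental.shape != predicted.shape:
        raise ValueError("flag_outliers: length mismatch")
    if ids is None:
        ids = [str(i) for i in range(experimental.size)]
    flags = []
    for i, (e, p) in enumerate(zip(experimental, predicted)):
        delta = e - p
        if np.isfinite(delta) and abs(delta) > threshold:
            flags.append(CurationFlag(parent_id=ids[i], flag_kind="outlier_single",
                                      evidence={"experimental": e, "predicted": p, "residual": delta}))
    return flags


def ensemble_flag(
    experimental,
    tool_predictions,
    ids=None,
    min_tools: int = 4,
    threshold: float = 1.0,
) -> list[CurationFlag]:
    """Flag items where at least ``min_tools`` prediction tools disagree with
    the experimental value by more than ``threshold``. Missing per-tool
    predictions (NaN) abstain for that item."""
    experimental = np.asarray(experimental, dtype=float)
    preds = np.asarray(tool_predictions, dtype=float)
    if preds.ndim != 2 or preds.shape[0] != experimental.size:
        raise ValueError("ensemble_flag: predictions must be (items x tools)")
    if preds.shape[1] < min_tools:
        raise ValueError(f"ensemble_flag: need >= {min_tools} tool columns")
    if ids is None:
        ids = [str(i) for i in range(experimental.size)]
    deltas = np.abs(experimental[:, None] - preds)
    disagree = np.nansum(deltas > threshold, axis=1)
    flags = []
    for i, count in enumerate(disagree):
        if count >= min_tools:
            flags.append(CurationFlag(parent_id=ids[i], flag_kind="outlier_ensemble",
                                      evidence={"n_disagreeing_tools": int(count),
                                                "n_tools": int(np.isfinite(deltas[i]).sum())}))
    return flags


@dataclass
class DuplicateGroup:
    kind: str  # duplicate_structure | duplicate_tautomer | duplicate_salt_pair
    member_ids: list[str]
    label_spread: float

    def to_flags(self) -> list[CurationFlag]:
        return [
            CurationFlag(parent_id=pid, flag_kind=self.kind,
                         evidence={"group": self.member_ids, "label_spread": self.label_spread})
            for pid in self.member_ids
        ]


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def find_duplicates(
    records: Sequence[MoleculeRecord],
    max_members: int = 32,
    max_depth: int = 4,
) -> list[DuplicateGroup]:
    """Group records that represent the same compound.

    Three linkage kinds, closed under union-find: identical heavy-atom graph,
    intersecting tautomer sets, and identical salt-stripped parent. Group
    kind priority when links mix: salt pair > tautomer > structure.
    """
    n = len(records)
    uf = _UnionFind(n)
    edge_kinds: dict[int, set[str]] = {}
    keys: list[str | None] = []
    taut_keys: list[set[str]] = []
    stripped_keys: list[str | None] = []
    salt_like: list[bool] = []
    for rec in records:
        mol = rec.mol()
        if mol is None:
            keys.append(None)
            taut_keys.append(set())
            stripped_keys.append(None)
            salt_like.append(False)
            continue
        keys.append(graph_key(mol))
        try:
            ts = enumerate_tautomers(mol, max_members=max_members, max_depth=max_depth)
            taut_keys.append({graph_key(s) for s in ts.members})
        except ValueError:
            taut_keys.append({graph_key(mol)})
        stripped = strip_salt(mol)
        stripped_keys.append(graph_key(stripped.parent) if not stripped.ambiguous else None)
        salt_like.append(bool(stripped.counterions))

    def connect(i, j, kind):
        uf.union(i, j)
        root = uf.find(i)
        edge_kinds.setdefault(root, set()).add(kind)

    for i in range(n):
        if keys[i] is None:
            continue
        for j in range(i + 1, n):
            if keys[j] is None:
                continue
            if keys[i] == keys[j]:
                connect(i, j, "structure")
            elif stripped_keys[i] is not None and stripped_keys[i] == stripped_keys[j] and (
                salt_like[i] or salt_like[j]
            ):
                connect(i, j, "salt")
            elif taut_keys[i] & taut_keys[j]:
                connect(i, j, "tautomer")

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    out = []
    for root, members in groups.items():
        if len(members) < 2:
            continue
        kinds = set()
        for m in members:
            kinds |= edge_kinds.get(uf.find(m), set())
        if "salt" in kinds:
            kind = "duplicate_salt_pair"
        elif "tautomer" in kinds:
            kind = "duplicate_tautomer"
        else:
            kind = "duplicate_structure"
        labels = [records[m].logp_exp for m in members if records[m].logp_exp is not None]
        spread = float(max(labels) - min(labels)) if len(labels) >= 2 else 0.0
        out.append(DuplicateGroup(kind=kind, member_ids=[records[m].id for m in members], label_spread=spread))
    return out


DEFAULT_NHA_BINS = (0.0, 10.0, 20.0, 30.0, float("inf"))


def rmse_by_nha(experimental, predicted, molecules, bin_edges=DEFAULT_NHA_BINS) -> pd.DataFrame:
    """Per-bin rmse over items whose heavy-atom count falls in [low, high).

    Empty bins are reported with n = 0 and NaN rmse. The pooled identity
    sum(n_b * rmse_b^2) = n * rmse^2 holds exactly.
    """
    experimental = np.asarray(experimental, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if not (len(experimental) == len(predicted) == len(molecules)):
        raise ValueError("rmse_by_nha: length mismatch")
    edges = list(bin_edges)
    if any(b >= c for b, c in zip(edges, edges[1:])):
        raise ValueError("rmse_by_nha: bin edges must increase")
    nha = np.array([count_nha(m) for m in molecules], dtype=float)
    sq = (experimental - predicted) ** 2
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        mask = (nha >= lo) & (nha < hi)
        n = int(mask.sum())
        rows.append({"nha_low": lo, "nha_high": hi, "n": n,
                     "rmse": float(np.sqrt(sq[mask].mean())) if n else float("nan")})
    return pd.DataFrame(rows)


def write_flags(flags: Sequence[CurationFlag], path) -> None:
    pd.DataFrame([f.to_row() for f in flags], columns=["parent_id", "flag_kind", "evidence"]).to_csv(
        path, index=False
    )
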