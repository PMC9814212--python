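"""pH-dependent ionization math: microstates, species fractions, log D,
macro log P, and ionization-class assignment from pKa windows.

Fractions use an independent-site model: each acidic or basic site titrates
with its own pKa ("pKb" values are pKas of the conjugate acid of the basic
site). All partition-coefficient mixing runs in log space so |log P| up to
several hundred cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from taulogp.dataset import IonClass

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class Microstate:
    """One protonation pattern: True = site protonated (acidic first)."""

    acidic_protonated: tuple[bool, ...]
    basic_protonated: tuple[bool, ...]

    @property
    def net_charge(self) -> int:
        return sum(self.basic_protonated) - sum(1 for p in self.acidic_protonated if not p)

    def label(self) -> str:
        a = "".join("H" if p else "-" for p in self.acidic_protonated)
        b = "".join("+" if p else "0" for p in self.basic_protonated)
        return f"A[{a}]B[{b}]" if (a or b) else "neutral"


def enumerate_microstates(n_acidic: int, n_basic: int) -> list[Microstate]:
    """All 2^(n_acidic+n_basic) protonation patterns, deterministic order
    (fully protonated first)."""
    if n_acidic < 0 or n_basic < 0:
        raise ValueError("site counts must be non-negative")
    states = []
    for a_pat in product([True, False], repeat=n_acidic):
        for b_pat in product([True, False], repeat=n_basic):
            states.append(Microstate(acidic_protonated=a_pat, basic_protonated=b_pat))
    return states


def species_fractions(
    pka_acidic: Sequence[float],
    pka_basic: Sequence[float],
    pH: float,
) -> np.ndarray:
    """Fraction of each microstate (order of :func:`enumerate_microstates`).

    Unnormalized log10-weight of a microstate is the sum of (pH - pKa) over
    its deprotonated sites; weights are normalized to sum to one. Computed
    in log space so extreme pH never underflows.
    """
    pka_acidic = [float(v) for v in pka_acidic]
    pka_basic = [float(v) for v in pka_basic]
    states = enumerate_microstates(len(pka_acidic), len(pka_basic))
    logw = np.empty(len(states))
    for i, st in enumerate(states):
        w = 0.0
        for pka, prot in zip(pka_acidic, st.acidic_protonated):
            if not prot:
                w += pH - pka
        for pka, prot in zip(pka_basic, st.basic_protonated):
            if not prot:
                w += pH - pka
        logw[i] = w
    logw *= _LN10
    return np.exp(logw - logsumexp(logw))


def log_d(logp_species: Sequence[float], fractions: Sequence[float]) -> float:
    """log10 of the fraction-weighted sum of partition coefficients:
    log D = log10(sum_i 10^logP_i * f_i), evaluated in log space."""
    logp_species = np.asarray(logp_species, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if logp_species.size == 0:
        raise ValueError("log_d: empty species list")
    if logp_species.shape != fractions.shape:
        raise ValueError("log_d: length mismatch")
    if np.any(fractions < 0):
        raise ValueError("log_d: negative fraction")
    mask = fractions > 0
    if not mask.any():
        raise ValueError("log_d: all fractions zero")
    terms = logp_species[mask] * _LN10 + np.log(fractions[mask])
    return float(logsumexp(terms) / _LN10)


@dataclass
class TautomerMixture:
    """Per-tautomer micro log P values with equilibrium fractions."""

    micro_logps: list[float]
    fractions: list[float]

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if len(self.micro_logps) != f.size:
            raise ValueError("mixture length mismatch")
        if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be non-negative and sum to 1")


def macro_logp(mixture: TautomerMixture) -> float:
    """Observable macro log P of a tautomer mixture; same kernel as log_d."""
    return log_d(mixture.micro_logps, mixture.fractions)


def classify_ionization(
    pka_acidic: Sequence[float] | None,
    pka_basic: Sequence[float] | None,
    window: tuple[float, float] = (3.0, 9.0),
    zwitterion_rule: str = "as_printed",
) -> IonClass:
    """Ionization class from pKa windows.

    A chemical is assumed measurable as the neutral species if some pH in
    ``window`` leaves it uncharged: an acidic pKa below the window low edge
    marks an anion, a basic pKa (conjugate-acid scale) above the high edge a
    cation. The zwitterion comparison is applied before the window checks.
    ``zwitterion_rule='as_printed'`` flags a zwitterion when the acidic pKa
    exceeds the basic pKa; ``'conventional'`` uses the opposite (chemically
    standard) direction. Multiprotic inputs use min acidic / max basic.
    """
    acidic = list(pka_acidic) if pka_acidic else []
    basic = list(pka_basic) if pka_basic else []
    if not acidic and not basic:
        return IonClass.UNKNOWN
    if zwitterion_rule not in ("as_printed", "conventional"):
        raise ValueError(f"unknown zwitterion_rule {zwitterion_rule!r}")
    if acidic and basic:
        pka, pkb = min(acidic), max(basic)
        is_zwit = pka > pkb if zwitterion_rule == "as_printed" else pkb > pka
        if is_zwit:
            return IonClass.ZWITTERION
    if acidic and min(acidic) < window[0]:
        return IonClass.ANION
    if basic and max(basic) > window[1]:
        return IonClass.CATION
    return IonClass.NEUTRAL


@dataclass
class SpeciationProfile:
    """Microstates of an ionizable molecule with per-pH fractions."""

    pka_acidic: list[float]
    pka_basic: list[float]
    logp_species: list[float] | None = None

    @property
    def microstates(self) -> list[Microstate]:
        return enumerate_microstates(len(self.pka_acidic), len(self.pka_basic))

    def fractions(self, pH: float) -> np.ndarray:
        return species_fractions(self.pka_acidic, self.pka_basic, pH)

    def log_d(self, pH: float) -> float:
        if self.logp_species is None:
            raise ValueError("no per-species log P values attached")
        return log_d(self.logp_species, self.fractions(pH))


def speciation_table(profile: SpeciationProfile, ph_grid: Sequence[float]) -> pd.DataFrame:
    """Fractions of every microstate over a pH grid; rows sum to 1."""
    states = profile.microstates
    rows = []
    for pH in ph_grid:
        fr = profile.fractions(float(pH))
        rows.append({"pH": float(pH), **{st.label(): f for st, f in zip(states, fr)}})
    return pd.DataFrame(rows)
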