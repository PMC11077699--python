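"""Protein physicochemical profiling: MW, pI, GRAVY, AI, II, classes.

Molecular weight, GRAVY and the instability index follow the standard
ProtParam formulas (via Biopython). The isoelectric point is a bisection
solver over a Henderson-Hasselbalch net-charge function on a swappable pKa
table (Bjellqvist values by default, the set the common web tools build on).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .sequence_io import ProteinSequence

__all__ = [
    "KYTE_DOOLITTLE",
    "BJELLQVIST_PKA",
    "PhysicochemicalProfile",
    "molecular_weight",
    "isoelectric_point",
    "net_charge",
    "gravy",
    "aliphatic_index",
    "instability_index",
    "acidity_class",
    "hydropathy_class",
    "profile",
    "profile_table",
]

#: Kyte-Doolittle hydropathy values (shared with the domain detectors).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

#: Bjellqvist pKa set: side chains plus generic termini. Swappable — every
#: charge/pI function accepts an alternative table of the same shape.
BJELLQVIST_PKA: dict[str, float] = {
    "Nterm": 7.5,
    "Cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.0,
    "Y": 10.0,
    "H": 5.98,
    "K": 10.0,
    "R": 12.0,
}

_POSITIVE = ("Nterm", "H", "K", "R")
_NEGATIVE = ("Cterm", "D", "E", "C", "Y")


@dataclass
class PhysicochemicalProfile:
    protein_id: str
    length: int
    molecular_weight: float
    pI: float
    gravy: float
    aliphatic_index: float
    instability_index: float
    acidity_class: str
    hydropathy_class: str


def _clean(p: ProteinSequence) -> str:
    # X residues are excluded from every index computation
    return p.residues.replace("X", "")


def molecular_weight(p: ProteinSequence) -> float:
    """Average (isotope-averaged) molecular weight in daltons."""
    seq = _clean(p)
    if not seq:
        raise ValueError(f"{p.protein_id}: no standard residues")
    return ProteinAnalysis(seq).molecular_weight()


def net_charge(p: ProteinSequence, pH: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge at ``pH`` over D,E,C,Y,H,K,R + termini."""
    pka = pka or BJELLQVIST_PKA
    seq = _clean(p)
    counts = {aa: seq.count(aa) for aa in "DECYHKR"}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    charge = 0.0
    for group in _POSITIVE:
        n = counts.get(group, 0)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - pka[group]))
    for group in _NEGATIVE:
        n = counts.get(group, 0)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - pH))
    return charge


def isoelectric_point(
    p: ProteinSequence,
    pka: dict[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """pH where the net charge crosses zero, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique.
    """
    lo, hi = 0.0, 14.0
    f_lo = net_charge(p, lo, pka)
    if f_lo <= 0:  # already non-positive at pH 0: pI at the boundary
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = net_charge(p, mid, pka)
        if abs(f_mid) < tol:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def gravy(p: ProteinSequence) -> float:
    """Grand average of hydropathicity: mean Kyte-Doolittle value."""
    seq = _clean(p)
    if not seq:
        raise ValueError(f"{p.protein_id}: no standard residues")
    return sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq)


def aliphatic_index(p: ProteinSequence) -> float:
    """AI = X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), X in mole percent."""
    seq = _clean(p)
    if not seq:
        raise ValueError(f"{p.protein_id}: no standard residues")
    n = len(seq)
    mole_pct = {aa: 100.0 * seq.count(aa) / n for aa in "AVIL"}
    return (
        mole_pct["A"]
        + 2.9 * mole_pct["V"]
        + 3.9 * (mole_pct["I"] + mole_pct["L"])
    )


def instability_index(p: ProteinSequence) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights."""
    seq = _clean(p)
    if len(seq) < 2:
        raise ValueError(f"{p.protein_id}: instability index needs length >= 2")
    return ProteinAnalysis(seq).instability_index()


def acidity_class(pI: float) -> str:
    """Partition of (0, 14): acidic < 6.5 <= neutral <= 7.5 < basic."""
    if not 0 < pI < 14:
        raise ValueError(f"pI {pI} outside (0, 14)")
    if pI > 7.5:
        return "basic"
    if pI >= 6.5:
        return "neutral"
    return "acidic"


def hydropathy_class(gravy_value: float) -> str:
    """Hydropathic iff GRAVY > 0, else hydrophilic."""
    return "hydropathic" if gravy_value > 0 else "hydrophilic"


def profile(p: ProteinSequence, pka: dict[str, float] | None = None) -> PhysicochemicalProfile:
    g = gravy(p)
    pi = isoelectric_point(p, pka)
    return PhysicochemicalProfile(
        protein_id=p.protein_id,
        length=len(_clean(p)),
        molecular_weight=molecular_weight(p),
        pI=pi,
        gravy=g,
        aliphatic_index=aliphatic_index(p),
        instability_index=instability_index(p),
        acidity_class=acidity_class(pi),
        hydropathy_class=hydropathy_class(g),
    )


def profile_table(proteins: dict[str, str], allow_unknown: bool = False) -> pd.DataFrame:
    """One profile row per protein from an id -> residues mapping."""
    rows = [
        vars(profile(ProteinSequence(pid, seq, allow_unknown=allow_unknown)))
        for pid, seq in proteins.items()
    ]
    return pd.DataFrame(rows)
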