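"""Codon-usage bias battery: RSCU, ENC, CAI, CBI, Fop, base composition.

All statistics operate on sense-codon counts (stops excluded; codons with
ambiguous bases are dropped at counting time). Internal codon spelling is
DNA (T); a renderer flag switches reports to RNA (U) spelling.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._genetic_code import (
    AA_TO_CODONS,
    CODON_TO_AA,
    DEGENERACY,
    STOP_CODONS,
    codons_of,
)

__all__ = [
    "CodonUsageProfile",
    "count_codons",
    "rscu",
    "enc",
    "cai",
    "cai_weights",
    "cbi",
    "fop",
    "third_position_composition",
    "optimal_codons",
    "profile_gene",
    "profile_table",
    "pooled_rscu_table",
    "index_correlations",
]

#: codons outside synonymous-variability statistics (single-codon amino acids)
_SINGLE_CODONS = frozenset(
    c for c, aa in CODON_TO_AA.items() if DEGENERACY[aa] == 1
)  # ATG (Met), TGG (Trp)

#: degeneracy classes Wright's ENC averages over, and class sizes in the
#: standard code (9 two-fold, 1 three-fold, 5 four-fold, 3 six-fold)
_ENC_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


def count_codons(cds: str) -> Counter[str]:
    """Sense-codon counts of one CDS; stops and N-containing codons skipped."""
    counts: Counter[str] = Counter()
    for codon in codons_of(cds.upper()):
        if codon in CODON_TO_AA:
            counts[codon] += 1
    return counts


def rscu(counts: Counter[str] | dict[str, int]) -> dict[str, float]:
    """Relative synonymous codon usage.

    RSCU(c) = count(c) / mean count over c's synonym family. Codons of
    amino acids absent from the gene are reported as 0 by convention.
    """
    out: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        total = sum(counts.get(c, 0) for c in codons)
        if total == 0:
            for c in codons:
                out[c] = 0.0
            continue
        mean = total / len(codons)
        for c in codons:
            out[c] = counts.get(c, 0) / mean
    return out


def enc(counts: Counter[str] | dict[str, int]) -> float:
    """Wright's effective number of codons (NC), in [20, 61] or NaN.

    Per amino acid with n > 1: F-hat = (n * sum p^2 - 1) / (n - 1). Class
    averages over degeneracy 2/3/4/6 use amino acids with F-hat > 0; ENC =
    2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, with the 3-fold class interpolated as
    (F2 + F4)/2 when absent. Missing required classes give NaN.
    """
    class_fhats: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in AA_TO_CODONS.items():
        k = len(codons)
        if k == 1:
            continue
        ns = [counts.get(c, 0) for c in codons]
        n = sum(ns)
        if n <= 1:
            continue
        sum_p2 = sum((x / n) ** 2 for x in ns)
        fhat = (n * sum_p2 - 1.0) / (n - 1.0)
        if fhat > 0:
            class_fhats[k].append(fhat)

    fbar: dict[int, float] = {}
    for k, fhats in class_fhats.items():
        if fhats:
            fbar[k] = sum(fhats) / len(fhats)
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    if any(k not in fbar for k in _ENC_CLASSES):
        return float("nan")
    value = 2.0 + sum(size / fbar[k] for k, size in _ENC_CLASSES.items())
    return min(value, 61.0)


def cai_weights(
    reference_counts: Counter[str] | dict[str, int], smoothing: float = 0.5
) -> dict[str, float]:
    """Relative adaptiveness weights from a reference gene set.

    w(c) = count(c) / max count within c's synonym family, with absent
    codons smoothed to ``smoothing`` pseudo-counts so no weight is zero.
    """
    weights: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) == 1:
            weights[codons[0]] = 1.0
            continue
        cs = [reference_counts.get(c, 0) or smoothing for c in codons]
        best = max(cs)
        for c, x in zip(codons, cs):
            weights[c] = x / best
    return weights


def cai(
    counts: Counter[str] | dict[str, int], reference_weights: dict[str, float]
) -> float:
    """Codon adaptation index: geometric mean of weights over the gene's
    codons, excluding single-codon amino acids (and stops)."""
    log_sum = 0.0
    n = 0
    for codon, count in counts.items():
        if count == 0 or codon in _SINGLE_CODONS:
            continue
        w = reference_weights.get(codon)
        if w is None or w <= 0:
            raise ValueError(
                f"codon {codon} has zero/absent CAI weight; rebuild the "
                "reference with 0.5-count smoothing (cai_weights smoothing=0.5)"
            )
        log_sum += count * math.log(w)
        n += count
    if n == 0:
        return float("nan")
    return math.exp(log_sum / n)


def _opt_counts(counts, optimal_set):
    """(N_opt, N_tot, N_ran) over degenerate amino acids only."""
    n_opt = n_tot = 0
    n_ran = 0.0
    for aa, codons in AA_TO_CODONS.items():
        k = len(codons)
        if k == 1:
            continue
        n_aa = sum(counts.get(c, 0) for c in codons)
        if n_aa == 0:
            continue
        k_opt = sum(1 for c in codons if c in optimal_set)
        n_opt += sum(counts.get(c, 0) for c in codons if c in optimal_set)
        n_tot += n_aa
        n_ran += n_aa * k_opt / k
    return n_opt, n_tot, n_ran


def fop(counts: Counter[str] | dict[str, int], optimal_set: set[str]) -> float:
    """Frequency of optimal codons: N_opt / N_tot over degenerate AAs."""
    n_opt, n_tot, _ = _opt_counts(counts, optimal_set)
    if n_tot == 0:
        return float("nan")
    return n_opt / n_tot


def cbi(counts: Counter[str] | dict[str, int], optimal_set: set[str]) -> float:
    """Codon bias index: (N_opt - N_ran) / (N_tot - N_ran)."""
    n_opt, n_tot, n_ran = _opt_counts(counts, optimal_set)
    if n_tot == 0 or abs(n_tot - n_ran) < 1e-12:
        return float("nan")
    return (n_opt - n_ran) / (n_tot - n_ran)


def third_position_composition(
    counts: Counter[str] | dict[str, int],
) -> dict[str, float]:
    """Base shares at third positions of synonymously variable codons.

    ATG, TGG (and stops, excluded upstream) do not contribute to the X3s
    shares or GC3s. ``gc`` is computed over all positions of all sense
    codons. Shares are NaN when no synonymously variable codon exists.
    """
    third: Counter[str] = Counter()
    all_bases: Counter[str] = Counter()
    for codon, n in counts.items():
        if n == 0:
            continue
        for b in codon:
            all_bases[b] += n
        if codon not in _SINGLE_CODONS:
            third[codon[2]] += n
    total_all = sum(all_bases.values())
    gc = (all_bases["G"] + all_bases["C"]) / total_all if total_all else float("nan")
    total3 = sum(third.values())
    if total3 == 0:
        nan = float("nan")
        return {"a3s": nan, "t3s": nan, "g3s": nan, "c3s": nan, "gc3s": nan, "gc": gc}
    shares = {b.lower() + "3s": third[b] / total3 for b in "ATGC"}
    shares["gc3s"] = (third["G"] + third["C"]) / total3
    shares["gc"] = gc
    return shares


@dataclass
class CodonUsageProfile:
    """Per-gene codon counts, RSCU table, and scalar bias indices."""

    gene_id: str
    codon_counts: dict[str, int] = field(repr=False)
    rscu: dict[str, float] = field(repr=False)
    enc: float = float("nan")
    cai: float = float("nan")
    cbi: float = float("nan")
    fop: float = float("nan")
    gc: float = float("nan")
    gc3s: float = float("nan")
    a3s: float = float("nan")
    t3s: float = float("nan")
    g3s: float = float("nan")
    c3s: float = float("nan")


def profile_gene(
    gene_id: str,
    cds: str,
    reference_weights: dict[str, float] | None = None,
    optimal_set: set[str] | None = None,
) -> CodonUsageProfile:
    counts = count_codons(cds)
    comp = third_position_composition(counts)
    return CodonUsageProfile(
        gene_id=gene_id,
        codon_counts=dict(counts),
        rscu=rscu(counts),
        enc=enc(counts),
        cai=cai(counts, reference_weights) if reference_weights else float("nan"),
        cbi=cbi(counts, optimal_set) if optimal_set else float("nan"),
        fop=fop(counts, optimal_set) if optimal_set else float("nan"),
        **comp,
    )


def optimal_codons(profiles: list[CodonUsageProfile]) -> set[str]:
    """Codons with pooled RSCU > 1 across the whole gene set."""
    pooled: Counter[str] = Counter()
    for p in profiles:
        pooled.update(p.codon_counts)
    return {c for c, v in rscu(pooled).items() if v > 1.0}


def pooled_rscu_table(profiles: list[CodonUsageProfile], rna: bool = False) -> pd.DataFrame:
    """61-row pooled RSCU table; ``rna`` renders U instead of T."""
    pooled: Counter[str] = Counter()
    for p in profiles:
        pooled.update(p.codon_counts)
    table = rscu(pooled)
    rows = [
        {
            "codon": c.replace("T", "U") if rna else c,
            "amino_acid": CODON_TO_AA[c],
            "count": pooled.get(c, 0),
            "rscu": table[c],
        }
        for c in sorted(CODON_TO_AA)
    ]
    return pd.DataFrame(rows)


_INDEX_COLS = ["a3s", "t3s", "g3s", "c3s", "gc3s", "gc", "cai", "cbi", "fop", "enc"]


def profile_table(profiles: list[CodonUsageProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        rows.append({"gene_id": p.gene_id, **{k: getattr(p, k) for k in _INDEX_COLS}})
    return pd.DataFrame(rows)


def index_correlations(profiles: list[CodonUsageProfile]) -> pd.DataFrame:
    """Pairwise Pearson correlations among the scalar indices.

    Missing values are handled pairwise-complete; zero-variance columns
    yield NaN entries rather than raising.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 profiles for correlations")
    df = profile_table(profiles)[_INDEX_COLS]
    corr = df.corr(method="pearson", min_periods=2)
    # diagonal is 1 by definition where the column has any data
    for c in corr.columns:
        if df[c].notna().any():
            corr.loc[c, c] = 1.0
    return corr
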