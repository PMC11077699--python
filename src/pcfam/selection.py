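"""Pairwise Ka/Ks by Nei-Gojobori (1986) counting with Jukes-Cantor
correction, plus tandem-duplication cluster detection from gene positions.

NG86 counts synonymous (S) and nonsynonymous (N) sites per codon as the
fraction of single-nucleotide changes that preserve the encoded amino
acid, and averages synonymous/nonsynonymous difference counts over all
equally weighted minimal mutational pathways between a codon pair.
Pathways passing through a stop codon are excluded with renormalization
(``count_stop_paths=True`` restores naive averaging for oracle checks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

from ._genetic_code import BASES, CODON_TO_AA, STOP_CODONS, codons_of
from .sequence_io import GeneModel

__all__ = [
    "KaKsResult",
    "TandemCluster",
    "ng86_sites",
    "ng86_differences",
    "kaks",
    "tandem_clusters",
]

_AMBIG = set("RYSWKMBDHVN-")


def _codon_ok(codon: str) -> bool:
    return not (set(codon) & _AMBIG) and codon in CODON_TO_AA


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 single changes at ``pos`` that are synonymous.

    Changes creating stop codons count as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0
    for b in BASES:
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if CODON_TO_AA.get(alt) == aa:
            syn += 1
    return syn / 3.0


def ng86_sites(cds: str) -> tuple[float, float]:
    """NG86 synonymous/nonsynonymous site counts (S, N) for one CDS.

    Codons containing ambiguity codes or gaps are excluded. The trailing
    stop codon, if present, is ignored.
    """
    S = N = 0.0
    codons = codons_of(cds.upper())
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for codon in codons:
        if not _codon_ok(codon):
            continue
        for pos in range(3):
            s = _syn_fraction(codon, pos)
            S += s
            N += 1.0 - s
    return S, N


def _codon_path_counts(
    a: str, b: str, count_stop_paths: bool = False
) -> tuple[float, float] | None:
    """Average (syn, nonsyn) step counts over minimal pathways a -> b.

    Returns None when every pathway crosses a stop codon (and stop paths
    are excluded) — the codon pair is then dropped by the caller.
    """
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    d = len(diff_positions)
    if d == 0:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_positions):
        current = a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS and not count_stop_paths:
                blocked = True
                break
            aa_from = CODON_TO_AA.get(current)
            aa_to = CODON_TO_AA.get(nxt)
            if aa_from is not None and aa_to is not None and aa_from == aa_to:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            totals.append((syn, nonsyn))
    if not totals:
        return None
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def ng86_differences(
    a: str, b: str, count_stop_paths: bool = False
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences (Sd, Nd)."""
    a, b = a.upper(), b.upper()
    if len(a) != len(b):
        raise ValueError("aligned CDS pair must have equal length")
    Sd = Nd = 0.0
    ca, cb = codons_of(a), codons_of(b)
    if ca and ca[-1] in STOP_CODONS and cb[-1] in STOP_CODONS:
        ca, cb = ca[:-1], cb[:-1]
    for ka, kb in zip(ca, cb):
        if not (_codon_ok(ka) and _codon_ok(kb)):
            continue
        counts = _codon_path_counts(ka, kb, count_stop_paths)
        if counts is None:
            continue
        Sd += counts[0]
        Nd += counts[1]
    return Sd, Nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return float("nan")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    """NG86 site counts, distances and selection call for one aligned pair."""

    pair: tuple[str, str]
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float
    ratio: float
    selection_class: str


def kaks(
    a: str,
    b: str,
    ids: tuple[str, str] = ("seq_a", "seq_b"),
    count_stop_paths: bool = False,
) -> KaKsResult:
    """Full NG86 Ka/Ks for one aligned CDS pair (symmetric in a, b).

    Site counts are averaged over the two sequences; proportions are
    Jukes-Cantor corrected. ``p >= 3/4`` saturates (NaN distance); Ks = 0
    leaves the ratio and selection class undefined.
    """
    a, b = a.upper(), b.upper()
    # exclude whole codons unusable in either sequence from both tallies
    ca, cb = codons_of(a), codons_of(b)
    keep = [
        i
        for i in range(len(ca))
        if _codon_ok(ca[i]) and _codon_ok(cb[i])
    ]
    fa = "".join(ca[i] for i in keep)
    fb = "".join(cb[i] for i in keep)
    Sa, Na = ng86_sites(fa)
    Sb, Nb = ng86_sites(fb)
    S, N = (Sa + Sb) / 2.0, (Na + Nb) / 2.0
    Sd, Nd = ng86_differences(fa, fb, count_stop_paths)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    if math.isnan(Ks) or math.isnan(Ka) or Ks == 0.0:
        ratio = float("nan")
        selection_class = "undefined"
    else:
        ratio = Ka / Ks
        if abs(ratio - 1.0) <= 1e-9:
            selection_class = "neutral"
        elif ratio < 1.0:
            selection_class = "purifying"
        else:
            selection_class = "positive"
    return KaKsResult(
        pair=ids, S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn,
        Ks=Ks, Ka=Ka, ratio=ratio, selection_class=selection_class,
    )


@dataclass
class TandemCluster:
    chromosome: str
    members: list[str]
    span: int


def tandem_clusters(
    genes: list[GeneModel],
    family_ids: set[str],
    max_separation: int = 250_000,
    max_intervening: int = 5,
) -> list[TandemCluster]:
    """Maximal chains of family genes forming tandem-duplication clusters.

    Consecutive family members must lie on the same chromosome, within
    ``max_separation`` bp (3' end to next 5' start) and with at most
    ``max_intervening`` non-family genes between them. Input genes must be
    sorted by (chromosome, start); clusters need >= 2 members.
    """
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start))
    clusters: list[TandemCluster] = []
    chain: list[GeneModel] = []
    intervening = 0

    def flush() -> None:
        if len(chain) >= 2:
            clusters.append(
                TandemCluster(
                    chromosome=chain[0].chromosome,
                    members=[g.gene_id for g in chain],
                    span=chain[-1].end - chain[0].start + 1,
                )
            )

    for g in ordered:
        if g.gene_id not in family_ids:
            intervening += 1
            continue
        if chain and (
            g.chromosome != chain[-1].chromosome
            or g.start - chain[-1].end > max_separation
            or intervening > max_intervening
        ):
            flush()
            chain = []
        chain.append(g)
        intervening = 0
    flush()
    return clusters
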