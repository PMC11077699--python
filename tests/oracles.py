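"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives a quantity by direct enumeration or grid search,
sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)
_BASES = "ACGT"


def brute_sites(codon: str) -> tuple[float, float]:
    """NG86 site counts of one codon by enumerating all 9 single changes."""
    syn = nonsyn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and _AA.get(alt) == _AA.get(codon):
                syn += 1
            else:
                nonsyn += 1
    return syn / 3.0, nonsyn / 3.0


def _paths(a: str, b: str):
    """Recursively enumerate all orderings of minimal mutational steps."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        yield []
        return
    for i in diffs:
        mid = a[:i] + b[i] + a[i + 1 :]
        for rest in _paths(mid, b):
            yield [(a, mid)] + rest


def brute_codon_diffs(
    a: str, b: str, count_stop_paths: bool = False
) -> tuple[float, float] | None:
    """Pathway-averaged (syn, nonsyn) steps between two codons."""
    totals = []
    for path in _paths(a, b):
        if not count_stop_paths and any(step[1] in _STOPS for step in path):
            continue
        syn = sum(1 for x, y in path if _AA.get(x) == _AA.get(y) and _AA.get(x))
        totals.append((syn, len(path) - syn))
    if not totals:
        return None
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def brute_pair_diffs(a: str, b: str) -> tuple[float, float]:
    Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in _STOPS or cb in _STOPS:
            continue
        r = brute_codon_diffs(ca, cb)
        if r is None:
            continue
        Sd += r[0]
        Nd += r[1]
    return Sd, Nd


def grid_search_pi(seq: str, pka: dict[str, float], step: float = 0.001) -> float:
    """pI as the grid pH minimizing |net charge| (vectorized HH sum)."""
    grid = np.arange(0.0, 14.0 + step, step)
    charge = np.zeros_like(grid)
    counts = {aa: seq.count(aa) for aa in "DECYHKR"}
    for group, n in [("Nterm", 1), ("H", counts["H"]), ("K", counts["K"]), ("R", counts["R"])]:
        if n:
            charge += n / (1.0 + 10.0 ** (grid - pka[group]))
    for group, n in [
        ("Cterm", 1),
        ("D", counts["D"]),
        ("E", counts["E"]),
        ("C", counts["C"]),
        ("Y", counts["Y"]),
    ]:
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[group] - grid))
    return float(grid[np.argmin(np.abs(charge))])


_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_RC = str.maketrans("ACGTN", "TGCAN")


def naive_scan(seq: str, name: str, consensus: str) -> set[tuple[str, int, int, str]]:
    """O(n*m) sliding-window IUPAC matcher on both strands; hits keyed
    (element, start, end, strand) on forward coordinates, palindromes
    reported once on the forward strand."""
    seq = seq.upper()
    n, w = len(seq), len(consensus)
    hits: set[tuple[str, int, int, str]] = set()
    fwd_spans = set()
    for i in range(n - w + 1):
        ok = True
        for j in range(w):
            if seq[i + j] not in _IUPAC[consensus[j]]:
                ok = False
                break
        if ok:
            hits.add((name, i + 1, i + w, "+"))
            fwd_spans.add((i + 1, i + w))
    rc = seq.translate(_RC)[::-1]
    for i in range(n - w + 1):
        ok = True
        for j in range(w):
            if rc[i + j] not in _IUPAC[consensus[j]]:
                ok = False
                break
        if ok:
            end = n - i
            start = end - w + 1
            if (start, end) not in fwd_spans:
                hits.add((name, start, end, "-"))
    return hits


def wright_enc(counts: dict[str, int]) -> float:
    """Direct restatement of Wright's ENC for cross-checking."""
    fam: dict[str, list[int]] = {}
    for codon, aa in _AA.items():
        fam.setdefault(aa, []).append(counts.get(codon, 0))
    per_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, ns in fam.items():
        k = len(ns)
        n = sum(ns)
        if k == 1 or n < 2:
            continue
        F = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        if F > 0:
            per_class[k].append(F)
    Fbar = {k: np.mean(v) for k, v in per_class.items() if v}
    if 3 not in Fbar and {2, 4} <= set(Fbar):
        Fbar[3] = (Fbar[2] + Fbar[4]) / 2
    if set(Fbar) != {2, 3, 4, 6}:
        return float("nan")
    return min(61.0, 2 + 9 / Fbar[2] + 1 / Fbar[3] + 5 / Fbar[4] + 3 / Fbar[6])
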