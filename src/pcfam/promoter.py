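"""Plant promoter cis-element scanning over an IUPAC consensus dictionary.

The shipped dictionary holds widely used published consensi for the light,
hormone, stress and flavonoid-regulation element classes; it is fully
replaceable by a user TSV (name, IUPAC consensus, category). Matching is
exhaustive on both strands with overlapping occurrences counted and
palindromic double-hits deduplicated by (element, start, end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ._genetic_code import reverse_complement

__all__ = [
    "CisElement",
    "CisElementHit",
    "IUPAC",
    "DEFAULT_ELEMENTS",
    "load_element_dictionary",
    "scan_promoter",
    "scan_promoters",
    "summarize_counts",
]

IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_CATEGORIES = ("light", "hormone", "stress", "flavonoid", "other")


@dataclass(frozen=True)
class CisElement:
    name: str
    consensus: str
    category: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError(f"{self.name}: consensus shorter than 4 bases")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC symbol(s) {sorted(bad)}")
        if self.category not in _CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")


@dataclass(frozen=True)
class CisElementHit:
    gene_id: str
    element: str
    start: int  # 1-based on the forward promoter coordinate
    end: int
    strand: str
    matched: str  # the matching-strand substring


#: default dictionary: standard published consensi, user-replaceable
DEFAULT_ELEMENTS: list[CisElement] = [
    CisElement("G-box", "CACGTG", "light"),
    CisElement("I-box", "GATAAG", "light"),
    CisElement("GT1-motif", "GGTTAA", "light"),
    CisElement("ABRE", "ACGTG", "hormone"),
    CisElement("TGACG-motif", "TGACG", "hormone"),
    CisElement("CGTCA-motif", "CGTCA", "hormone"),
    CisElement("TCA-element", "CCATCTTTTT", "hormone"),
    CisElement("GARE-motif", "TCTGTTG", "hormone"),
    CisElement("P-box", "CCTTTTG", "hormone"),
    CisElement("AuxRE", "TGTCTC", "hormone"),
    CisElement("ARE", "AAACCA", "stress"),
    CisElement("LTR", "CCGAAA", "stress"),
    CisElement("MBS", "CAACTG", "stress"),
    CisElement("DRE", "RCCGAC", "stress"),
    CisElement("as-1", "TGACG", "hormone"),
    CisElement("MBSI", "AAAAAACSGTTA", "flavonoid"),
]

#: element names counted as MeJA-responsive (the TGACG/CGTCA pair)
MEJA_ELEMENTS = frozenset({"TGACG-motif", "CGTCA-motif"})


def load_element_dictionary(path: str | Path | None = None) -> list[CisElement]:
    """Load the element dictionary from a TSV (name, consensus, category),
    or return the built-in default."""
    if path is None:
        return list(DEFAULT_ELEMENTS)
    elements = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"element row needs 3 columns: {line!r}")
            name, consensus, category = parts
            elements.append(CisElement(name, consensus.upper(), category))
    if not elements:
        raise ValueError(f"empty element dictionary: {path}")
    return elements


def _iupac_regex(consensus: str) -> re.Pattern[str]:
    # lookahead so overlapping occurrences are all found
    body = "".join(
        f"[{IUPAC[s]}]" if len(IUPAC[s]) > 1 else IUPAC[s] for s in consensus.upper()
    )
    return re.compile(f"(?=({body}))")


def scan_promoter(
    promoter: str, elements: list[CisElement], gene_id: str = ""
) -> list[CisElementHit]:
    """All element occurrences on both strands of one promoter.

    Positions are 1-based on the forward coordinate system; a palindromic
    match found on both strands is reported once (forward).
    """
    seq = promoter.upper()
    if not seq:
        raise ValueError("empty promoter")
    n = len(seq)
    rc = reverse_complement(seq)
    hits: list[CisElementHit] = []
    for el in elements:
        pat = _iupac_regex(el.consensus)
        width = len(el.consensus)
        seen: set[tuple[int, int]] = set()
        for m in pat.finditer(seq):
            start = m.start() + 1
            seen.add((start, start + width - 1))
            hits.append(
                CisElementHit(gene_id, el.name, start, start + width - 1, "+", m.group(1))
            )
        for m in pat.finditer(rc):
            # map reverse-strand match back to forward coordinates
            end = n - m.start()
            start = end - width + 1
            if (start, end) in seen:
                continue  # palindrome already counted on the forward strand
            hits.append(CisElementHit(gene_id, el.name, start, end, "-", m.group(1)))
    hits.sort(key=lambda h: (h.element, h.start))
    return hits


def scan_promoters(
    promoters: dict[str, str], elements: list[CisElement]
) -> dict[str, list[CisElementHit]]:
    return {gid: scan_promoter(seq, elements, gid) for gid, seq in promoters.items()}


def summarize_counts(
    hits_by_gene: dict[str, list[CisElementHit]], elements: list[CisElement]
) -> pd.DataFrame:
    """Gene x element count matrix with per-category total columns."""
    names = [el.name for el in elements]
    rows = []
    for gid, hits in hits_by_gene.items():
        row = {"gene_id": gid, **{name: 0 for name in names}}
        for h in hits:
            row[h.element] += 1
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(columns=names)
    for cat in _CATEGORIES:
        members = [el.name for el in elements if el.category == cat]
        if members:
            df[f"total_{cat}"] = df[members].sum(axis=1)
    return df
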