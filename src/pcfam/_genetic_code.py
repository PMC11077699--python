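"""Standard genetic code lookups shared across modules.

Built once from Biopython's standard DNA codon table so every module
(translation, codon-usage statistics, NG86 site counting, the synthetic
generator) agrees on the same code.
"""

from __future__ import annotations

from Bio.Data import CodonTable

_STD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, 61 sense codons, DNA spelling (T not U)
CODON_TO_AA: dict[str, str] = dict(_STD.forward_table)

STOP_CODONS: frozenset[str] = frozenset(_STD.stop_codons)

#: amino acid -> tuple of synonymous codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)

#: amino acid -> degeneracy (number of synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cs) for aa, cs in AA_TO_CODONS.items()}

#: the 20 standard one-letter residue codes
AMINO_ACIDS: frozenset[str] = frozenset(AA_TO_CODONS)

BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def codons_of(cds: str) -> list[str]:
    """Split a CDS into consecutive codons; length must be a multiple of 3."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]
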