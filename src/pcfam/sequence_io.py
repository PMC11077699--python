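"""Sequence and gene-model I/O: FASTA, flat GFF3, translation, promoters.

Coordinates are 1-based inclusive throughout (GFF3 convention); conversion
to Python slices happens only inside the functions of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._genetic_code import CODON_TO_AA, STOP_CODONS, codons_of, reverse_complement

__all__ = [
    "GeneModel",
    "ProteinSequence",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "translate",
    "reverse_complement",
    "extract_promoter",
]


@dataclass
class GeneModel:
    """A gene's location and coding sequence.

    ``start``/``end`` are 1-based inclusive chromosome coordinates and the
    anchor for promoter extraction and tandem-cluster detection.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str = ""

    def __post_init__(self) -> None:
        if self.start <= 0 or self.end <= 0:
            raise ValueError(f"{self.gene_id}: coordinates must be positive")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.cds = self.cds.upper()

    def validate_cds(self, require_atg: bool = True) -> None:
        """Check the CDS is a translatable open reading frame.

        Raises ``ValueError`` on length not divisible by 3, missing ATG
        start (when ``require_atg``), or an internal stop codon.
        """
        if not self.cds:
            raise ValueError(f"{self.gene_id}: empty CDS")
        if len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if require_atg and not self.cds.startswith("ATG"):
            raise ValueError(f"{self.gene_id}: CDS does not begin with ATG")
        for i, codon in enumerate(codons_of(self.cds)):
            if codon in STOP_CODONS and i < len(self.cds) // 3 - 1:
                raise ValueError(f"{self.gene_id}: internal stop codon at codon {i + 1}")


@dataclass
class ProteinSequence:
    """A protein over the 20 standard one-letter codes.

    ``X`` is tolerated only with ``allow_unknown`` and is excluded from all
    downstream index computations.
    """

    protein_id: str
    residues: str
    allow_unknown: bool = False

    _STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"{self.protein_id}: empty protein sequence")
        allowed = self._STANDARD | ({"X"} if self.allow_unknown else set())
        bad = set(self.residues) - allowed
        if bad:
            raise ValueError(
                f"{self.protein_id}: non-standard residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase-sequence mapping.

    Ids are the first whitespace-delimited header token; record order is
    preserved (dicts are ordered). Duplicate ids and empty files are errors.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA id: {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path: str | Path, records: dict[str, str], width: int = 60) -> None:
    """Write an id -> sequence mapping as FASTA wrapped at ``width`` columns."""
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs = {}
    for part in col9.strip().rstrip(";").split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path, feature: str = "gene") -> list[GeneModel]:
    """Read GFF3 gene models of one feature type, sorted by (chromosome, start).

    Returns :class:`GeneModel` skeletons (no CDS attached). Coordinates are
    kept 1-based inclusive as printed. A missing ``ID`` attribute or
    ``start > end`` raises with the offending line number.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"line {lineno}: expected 9 tab-separated columns")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != feature:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise ValueError(f"line {lineno}: start {start_i} > end {end_i}")
            attributes = _parse_attributes(attrs)
            if "ID" not in attributes:
                raise ValueError(f"line {lineno}: missing ID attribute")
            genes.append(
                GeneModel(attributes["ID"], chrom, start_i, end_i, strand)
            )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return genes


def write_gff3(path: str | Path, genes: list[GeneModel], feature: str = "gene") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chromosome}\tpcfam\t{feature}\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def translate(cds: str, allow_unknown: bool = False) -> str:
    """Translate a CDS with the standard code.

    A trailing stop codon is dropped; an internal stop is an error. Codons
    containing ambiguous bases translate to ``X`` when ``allow_unknown``,
    otherwise raise.
    """
    cds = cds.upper()
    codons = codons_of(cds)
    residues = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i == len(codons) - 1:
                break
            raise ValueError(f"internal stop codon {codon} at codon {i + 1}")
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            if allow_unknown:
                aa = "X"
            else:
                raise ValueError(f"ambiguous codon {codon} at codon {i + 1}")
        residues.append(aa)
    return "".join(residues)


def extract_promoter(
    gene: GeneModel, genome: dict[str, str], length: int = 2000
) -> tuple[str, bool]:
    """Strand-aware upstream window of ``length`` bp, 5' of the gene feature.

    On the plus strand this is ``genome[start-length .. start-1]``; on the
    minus strand the reverse complement of ``genome[end+1 .. end+length]``.
    Windows running off the chromosome are truncated (flag returned True).
    """
    if gene.chromosome not in genome:
        raise KeyError(f"unknown chromosome {gene.chromosome!r} for {gene.gene_id}")
    chrom = genome[gene.chromosome]
    if gene.strand == "+":
        lo = max(gene.start - length, 1)
        window = chrom[lo - 1 : gene.start - 1]
        truncated = gene.start - length < 1
        return window, truncated
    hi = min(gene.end + length, len(chrom))
    window = chrom[gene.end : hi]
    truncated = gene.end + length > len(chrom)
    return reverse_complement(window), truncated
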