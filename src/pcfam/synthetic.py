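"""Synthetic phytocyanin families with planted ground truth.

Generates multi-chromosome genomes whose genes carry planted SP / PLCD /
ALR / GAS domain architectures with specified copper-ligand residues,
CDSs with tunable codon bias, 2 kb promoters with planted cis-elements,
duplicate gene pairs with controlled synonymous/nonsynonymous divergence,
and qPCR Ct tables with known fold changes — so every downstream stage of
the pipeline can be tested against construction-time truth.

Determinism: all randomness flows from one integer seed through a named
generator per output stream (one stream per gene, per promoter, per
locus), so generated genes are byte-stable under extension of the family.

Domain templates (residue alphabets chosen so each heuristic detector has
exactly one deterministic target per planted domain):

* SP: M + 10 x {L,V,A,I,F} + 4 polar residues (15 aa).
* PLCD (54 aa): H x30 C x9 C x5 H x5 Z with Z = M (UCL/PLCL), Q (SCL) or
  {A,S,G} (ENODL, incomplete copper site); the first Cys is the disulfide
  scaffold 10 before the ligand Cys.
* ALR: 30 aa, 20 of them P/A/S/T (any 20-residue window >= 50% PAST).
* GAS: 25 aa with a small omega residue 22 from the C-terminus and a
  hydrophobic {L,V,I,F} 12-residue tail.
* Inter-domain linkers and padding use hydrophilic filler {D,E,K,N,G,R}
  that contains no His/Cys/Met/Gln, no P/A/S/T and no hydrophobic runs,
  so no spurious domain can arise outside the planted spans.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._genetic_code import (
    AA_TO_CODONS,
    BASES,
    CODON_TO_AA,
    STOP_CODONS,
    codons_of,
    reverse_complement,
)
from .classifier import DomainAnnotation, LigandSet, Span
from .promoter import DEFAULT_ELEMENTS, CisElement, scan_promoter
from .sequence_io import GeneModel, translate

__all__ = [
    "FamilySimConfig",
    "GeneTruth",
    "SyntheticFamily",
    "generate_family",
    "mutate_pair",
    "generate_ct_table",
]

FILLER = "DEKNGR"
HYDROPHOBIC_CORE = "LVAIF"
SP_POLAR = "STND"
GAS_TAIL = "LVIF"
GAS_SPACER = "EKR"  # omega-free so the planted omega is the unique candidate
OMEGA = "GAS"
PAST = "PAST"

_SP_TYPES = frozenset("I II III IV V".split())
_ALR_TYPES = frozenset("I II III VI VII".split())
_GAS_TYPES = frozenset("I II V VI VII".split())
_TWO_PLCD_TYPES = frozenset(("I", "VII"))

LINKER_LEN = 25
SP_LEN = 15
PLCD_LEN = 54
ALR_LEN = 30
GAS_LEN = 25
PROMOTER_LEN = 2000
LOCUS_PAD = 3000

#: designated (preferred) codon per amino acid for reverse translation:
#: alphabetically first synonym, fixed so the optimal-codon truth is stable
DESIGNATED_CODONS: dict[str, str] = {aa: cs[0] for aa, cs in AA_TO_CODONS.items()}


def _rng(seed: int, *stream: str) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF] + [zlib.crc32(s.encode()) for s in stream]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _choice_str(rng: np.random.Generator, alphabet: str, n: int) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


@dataclass
class FamilySimConfig:
    """Study-condition defaults: a 59-gene family on 12 chromosomes with
    the observed subfamily imbalance, moderate codon bias, a mixed
    light/hormone/stress promoter load, and purifying-regime duplicate
    pairs."""

    n_genes: int = 59
    n_chromosomes: int = 12
    subfamily_mix: dict[str, float] = field(
        default_factory=lambda: {
            "ENODL": 33 / 59,
            "SCL": 13 / 59,
            "UCL": 9 / 59,
            "PLCL": 4 / 59,
        }
    )
    type_mix: dict[str, float] = field(
        default_factory=lambda: {
            "I": 4 / 59, "II": 30 / 59, "III": 10 / 59, "IV": 5 / 59,
            "V": 1 / 59, "VI": 6 / 59, "VII": 1 / 59, "VIII": 2 / 59,
        }
    )
    cds_length_range: tuple[int, int] = (120, 360)  # codons
    codon_bias_strength: float = 0.55
    planted_elements: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("G-box", 2),
            ("ABRE", 1),
            ("TGACG-motif", 1),
            ("MBS", 1),
            ("LTR", 1),
        ]
    )
    pair_divergence: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.20, 0.03), (0.12, 0.02), (0.06, 0.01)]
    )
    seed: int = 0
    element_dictionary: list[CisElement] = field(
        default_factory=lambda: list(DEFAULT_ELEMENTS)
    )

    def __post_init__(self) -> None:
        for name, mix in (("subfamily_mix", self.subfamily_mix), ("type_mix", self.type_mix)):
            s = sum(mix.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {s}, expected 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"{name} has negative proportions")
        if self.cds_length_range[0] < 120:
            raise ValueError("cds_length_range minimum is 120 codons")
        if self.n_genes < 1 or self.n_chromosomes < 1:
            raise ValueError("n_genes and n_chromosomes must be positive")
        known = {el.name for el in self.element_dictionary}
        for name, copies in self.planted_elements:
            if name not in known:
                raise ValueError(f"planted element {name!r} not in dictionary")
            if copies < 0:
                raise ValueError("planted copies must be >= 0")
        # subfamily/type compatibility: UCL needs ALR types, PLCL ALR-free
        if self.subfamily_mix.get("PLCL", 0) > 0 and not any(
            self.type_mix.get(t, 0) > 0 for t in ("IV", "V", "VIII")
        ):
            raise ValueError("PLCL requires an ALR-free type (IV, V or VIII) in type_mix")
        if self.subfamily_mix.get("UCL", 0) > 0 and not any(
            self.type_mix.get(t, 0) > 0 for t in _ALR_TYPES
        ):
            raise ValueError("UCL requires an ALR-bearing type in type_mix")


@dataclass
class GeneTruth:
    """Construction-time ground truth for one generated gene."""

    gene_id: str
    chromosome: str
    strand: str
    subfamily: str
    type: str
    sp: Span | None
    plcd_spans: list[Span]
    ligand_sets: list[LigandSet]
    alr: Span | None
    gas: Span | None
    planted_positions: dict[str, list[int]]  # element -> promoter starts
    expected_element_counts: dict[str, int]  # incl. cross-matching elements
    partner: str | None = None
    syn_changes: int = 0
    nonsyn_changes: int = 0

    def to_domain_annotation(self, length: int) -> DomainAnnotation:
        return DomainAnnotation(
            protein_id=self.gene_id,
            length=length,
            sp=self.sp,
            plcd_spans=list(self.plcd_spans),
            ligand_sets=list(self.ligand_sets),
            disulfide_cys=sorted(
                {ls.c[1] - 10 for ls in self.ligand_sets if ls.c}
                | {ls.c[1] for ls in self.ligand_sets if ls.c}
            ),
            alr=self.alr,
            gas=self.gas,
            nglyc_sites=[],
        )


@dataclass
class SyntheticFamily:
    genome: dict[str, str]
    genes: list[GeneModel]
    proteins: dict[str, str]
    truth: dict[str, GeneTruth]
    config: FamilySimConfig

    def truth_annotations(self) -> dict[str, DomainAnnotation]:
        return {
            gid: t.to_domain_annotation(len(self.proteins[gid]))
            for gid, t in self.truth.items()
        }

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth.values():
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "chromosome": t.chromosome,
                    "strand": t.strand,
                    "subfamily": t.subfamily,
                    "type": t.type,
                    "n_plcd": len(t.plcd_spans),
                    "has_sp": t.sp is not None,
                    "has_alr": t.alr is not None,
                    "has_gas": t.gas is not None,
                    "partner": t.partner or ".",
                    "syn_changes": t.syn_changes,
                    "nonsyn_changes": t.nonsyn_changes,
                    "planted_elements": ";".join(
                        f"{k}:{len(v)}" for k, v in sorted(t.planted_positions.items())
                    )
                    or ".",
                }
            )
        return pd.DataFrame(rows)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .sequence_io import write_fasta, write_gff3

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fna",
            "gff3": outdir / "genes.gff3",
            "proteins": outdir / "proteins.faa",
            "cds": outdir / "cds.fna",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(paths["genome"], self.genome)
        write_gff3(paths["gff3"], self.genes)
        write_fasta(paths["proteins"], self.proteins)
        write_fasta(paths["cds"], {g.gene_id: g.cds for g in self.genes})
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# label apportionment (largest remainder, deterministic)

def _apportion(n: int, mix: dict[str, float]) -> dict[str, int]:
    quotas = {k: n * p for k, p in mix.items()}
    counts = {k: int(q) for k, q in quotas.items()}
    short = n - sum(counts.values())
    by_frac = sorted(quotas, key=lambda k: (-(quotas[k] - counts[k]), k))
    for k in by_frac[:short]:
        counts[k] += 1
    return counts


def _restricted_type_counts(
    subfamily: str, count: int, type_mix: dict[str, float]
) -> dict[str, int]:
    if subfamily == "UCL":
        allowed = _ALR_TYPES
    elif subfamily == "PLCL":
        allowed = {"IV", "V", "VIII"}
    else:
        allowed = set(type_mix)
    restricted = {t: p for t, p in type_mix.items() if t in allowed and p > 0}
    total = sum(restricted.values())
    if total == 0:
        raise ValueError(f"no compatible type for subfamily {subfamily}")
    return _apportion(count, {t: p / total for t, p in restricted.items()})


# ---------------------------------------------------------------------------
# protein construction

def _plcd_block(rng: np.random.Generator, z: str) -> str:
    return (
        "H"
        + _choice_str(rng, FILLER, 30)
        + "C"
        + _choice_str(rng, FILLER, 9)
        + "C"
        + _choice_str(rng, FILLER, 5)
        + "H"
        + _choice_str(rng, FILLER, 5)
        + z
    )


def _build_protein(
    rng: np.random.Generator, subfamily: str, type_: str, target_len: int
) -> tuple[str, dict]:
    """Assemble one protein; returns (sequence, truth spans)."""
    has_sp = type_ in _SP_TYPES
    has_alr = type_ in _ALR_TYPES
    has_gas = type_ in _GAS_TYPES
    n_plcd = 2 if type_ in _TWO_PLCD_TYPES else 1

    if subfamily == "SCL":
        z_residues = ["Q"] * n_plcd
    elif subfamily == "ENODL":
        z_residues = [str(rng.choice(list(OMEGA))) for _ in range(n_plcd)]
    else:  # UCL / PLCL
        z_residues = ["M"] * n_plcd

    pieces: list[tuple[str, str]] = []  # (kind, sequence)
    if has_sp:
        sp_seq = "M" + _choice_str(rng, HYDROPHOBIC_CORE, 10) + _choice_str(rng, SP_POLAR, 4)
        pieces.append(("sp", sp_seq))
    else:
        pieces.append(("nterm", "M" + _choice_str(rng, FILLER, 5)))
    for i in range(n_plcd):
        pieces.append(("linker", _choice_str(rng, FILLER, LINKER_LEN)))
        pieces.append((f"plcd{i}", _plcd_block(rng, z_residues[i])))
    pieces.append(("pad", ""))  # placeholder, filled below
    if has_alr:
        past = [str(rng.choice(list(PAST))) for _ in range(20)]
        other = [str(rng.choice(list(FILLER))) for _ in range(ALR_LEN - 20)]
        block = past + other
        rng.shuffle(block)
        pieces.append(("alr", "".join(block)))
    if has_gas:
        pieces.append(("linker", _choice_str(rng, FILLER, LINKER_LEN)))
        gas_seq = (
            _choice_str(rng, GAS_SPACER, 3)
            + str(rng.choice(list(OMEGA)))
            + _choice_str(rng, GAS_SPACER, 9)
            + _choice_str(rng, GAS_TAIL, 12)
        )
        pieces.append(("gas", gas_seq))

    pad_len = max(target_len - sum(len(s) for _, s in pieces), LINKER_LEN)
    pieces = [
        (kind, _choice_str(rng, FILLER, pad_len) if kind == "pad" else s)
        for kind, s in pieces
    ]

    seq_parts: list[str] = []
    spans: dict = {"sp": None, "plcd": [], "ligands": [], "alr": None, "gas": None}
    cursor = 1
    for kind, s in pieces:
        start, end = cursor, cursor + len(s) - 1
        if kind == "sp":
            spans["sp"] = (start, end)
        elif kind.startswith("plcd"):
            spans["plcd"].append((start, end))
            off = start - 1
            complete = subfamily != "ENODL"
            z_slot = (s[53], off + 54) if complete else None
            spans["ligands"].append(
                LigandSet(
                    h1=("H", off + 1),
                    c=("C", off + 42),
                    h2=("H", off + 48),
                    z=z_slot,
                    complete=complete,
                )
            )
        elif kind == "alr":
            spans["alr"] = (start, end)
        elif kind == "gas":
            spans["gas"] = (start, end)
        seq_parts.append(s)
        cursor = end + 1
    return "".join(seq_parts), spans


def _reverse_translate(
    protein: str, rng: np.random.Generator, bias: float,
    designated: dict[str, str] | None = None,
) -> str:
    designated = designated or DESIGNATED_CODONS
    out = []
    for aa in protein:
        codons = AA_TO_CODONS[aa]
        if len(codons) == 1:
            out.append(codons[0])
            continue
        if rng.random() < bias:
            out.append(designated[aa])
        else:
            others = [c for c in codons if c != designated[aa]]
            out.append(str(rng.choice(others)))
    return "".join(out)


# ---------------------------------------------------------------------------
# promoter construction

def _realize_iupac(consensus: str, rng: np.random.Generator) -> str:
    from .promoter import IUPAC

    return "".join(
        s if len(IUPAC[s]) == 1 else str(rng.choice(list(IUPAC[s])))
        for s in consensus
    )


def _expected_hits_of_oligo(
    oligo: str, start: int, elements: list[CisElement]
) -> set[tuple[str, int, int, str]]:
    """All dictionary hits wholly inside a planted oligo, shifted to the
    promoter coordinate system (cross-matching elements included)."""
    hits = scan_promoter(oligo, elements, gene_id="oligo")
    return {
        (h.element, start + h.start - 1, start + h.end - 1, h.strand) for h in hits
    }


def _build_promoter(
    rng: np.random.Generator,
    elements: list[CisElement],
    planted: list[tuple[str, int]],
    length: int = PROMOTER_LEN,
    max_iter: int = 300,
) -> tuple[str, dict[str, list[int]], dict[str, int]]:
    """Random promoter with exactly the planted element content.

    Background is scrubbed of every incidental dictionary hit, then the
    planted copies are inserted at non-overlapping positions; junction
    artifacts are re-randomized until the scan equals the expected hit set
    (planted oligos plus their deterministic cross-matches).
    """
    by_name = {el.name: el for el in elements}
    seq = list(_choice_str(rng, BASES, length))

    # scrub incidental background hits
    for _ in range(max_iter):
        hits = scan_promoter("".join(seq), elements)
        if not hits:
            break
        for h in hits:
            for i in range(h.start - 1, h.end):
                seq[i] = str(rng.choice(list(BASES)))
    else:
        raise RuntimeError("promoter background scrub did not converge")

    clean_bg = list(seq)
    for attempt in range(max_iter):
        seq = list(clean_bg)
        # choose non-overlapping positions for every planted copy
        occupied: list[tuple[int, int]] = []
        positions: dict[str, list[int]] = {name: [] for name, _ in planted}
        expected: set[tuple[str, int, int, str]] = set()
        ok = True
        for name, copies in planted:
            width = len(by_name[name].consensus)
            for _ in range(copies):
                for _try in range(200):
                    start = int(rng.integers(1, length - width + 1))
                    end = start + width - 1
                    if all(end < s - 1 or start > e + 1 for s, e in occupied):
                        break
                else:
                    ok = False
                    break
                oligo = _realize_iupac(by_name[name].consensus, rng)
                for i, b in enumerate(oligo):
                    seq[start - 1 + i] = b
                occupied.append((start, end))
                positions[name].append(start)
                expected |= _expected_hits_of_oligo(oligo, start, elements)
            if not ok:
                break
        if not ok:
            continue
        # kill junction artifacts outside planted spans
        for _ in range(max_iter):
            actual = {
                (h.element, h.start, h.end, h.strand)
                for h in scan_promoter("".join(seq), elements)
            }
            extra = actual - expected
            if not extra and expected - actual == set():
                counts: dict[str, int] = {}
                for el_name, *_ in expected:
                    counts[el_name] = counts.get(el_name, 0) + 1
                return "".join(seq), positions, counts
            overlap_planted = False
            for el_name, s, e, _strand in extra:
                if any(not (e < os or s > oe) for os, oe in occupied):
                    overlap_planted = True
                    break
                for i in range(s - 1, e):
                    seq[i] = str(rng.choice(list(BASES)))
            if overlap_planted or expected - actual:
                break  # replant from scratch
    raise RuntimeError("promoter planting did not converge")


# ---------------------------------------------------------------------------
# pair divergence

def mutate_pair(
    cds: str,
    syn_changes: int,
    nonsyn_changes: int,
    seed: int,
    allowed_codons: set[int] | None = None,
    forbidden_residues: set[str] | None = None,
) -> tuple[str, list[dict]]:
    """Introduce exact counts of verified synonymous / nonsynonymous
    single-nucleotide changes at distinct codons.

    ``allowed_codons`` (0-based codon indices) restricts where
    nonsynonymous changes may fall; ``forbidden_residues`` excludes
    substitutions creating those amino acids. No stop codons are ever
    created. Returns the mutated CDS and a change log with one entry per
    introduced change.
    """
    rng = _rng(seed, "mutate_pair")
    codons = codons_of(cds.upper())
    forbidden = forbidden_residues or set()

    def options(idx: int, want_syn: bool) -> list[tuple[int, str, str]]:
        codon = codons[idx]
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            return []
        opts = []
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                alt = codon[:pos] + b + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                alt_aa = CODON_TO_AA[alt]
                if want_syn and alt_aa == aa:
                    opts.append((pos, b, alt))
                elif not want_syn and alt_aa != aa and alt_aa not in forbidden:
                    opts.append((pos, b, alt))
        return opts

    n_codons = len(codons)
    last = n_codons - 1 if codons[-1] in STOP_CODONS else n_codons
    all_idx = list(range(last))
    syn_pool = [i for i in all_idx if options(i, True)]
    nonsyn_pool = [
        i
        for i in all_idx
        if (allowed_codons is None or i in allowed_codons) and options(i, False)
    ]
    if len(syn_pool) < syn_changes:
        raise ValueError(
            f"requested {syn_changes} synonymous changes but only "
            f"{len(syn_pool)} codons offer one"
        )

    chosen_syn = [int(i) for i in rng.choice(syn_pool, size=syn_changes, replace=False)] if syn_changes else []
    remaining = [i for i in nonsyn_pool if i not in set(chosen_syn)]
    if len(remaining) < nonsyn_changes:
        raise ValueError(
            f"requested {nonsyn_changes} nonsynonymous changes but only "
            f"{len(remaining)} eligible codons remain"
        )
    chosen_nonsyn = (
        [int(i) for i in rng.choice(remaining, size=nonsyn_changes, replace=False)]
        if nonsyn_changes
        else []
    )

    log: list[dict] = []
    mutated = list(codons)
    for idx, category in [(i, "synonymous") for i in chosen_syn] + [
        (i, "nonsynonymous") for i in chosen_nonsyn
    ]:
        opts = options(idx, category == "synonymous")
        pos, b, alt = opts[int(rng.integers(len(opts)))]
        log.append(
            {
                "codon_index": idx,
                "nt_position": idx * 3 + pos + 1,
                "ref": mutated[idx][pos],
                "alt": b,
                "category": category,
            }
        )
        mutated[idx] = alt
    log.sort(key=lambda e: e["nt_position"])
    return "".join(mutated), log


# ---------------------------------------------------------------------------
# Ct tables

def generate_ct_table(
    n_genes: int,
    n_stages: int,
    fold_changes: np.ndarray,
    ref_ct: float = 20.0,
    noise_sd: float = 0.2,
    replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct table with known fold changes (calibrator = first stage).

    Target Ct = calibrator target Ct - log2(fold) + N(0, noise_sd);
    reference-gene Ct = ref_ct + noise. Stage names follow the DAF
    (days after bag removal) axis: DAF1, DAF5, ... Returns (Ct table,
    truth fold matrix).
    """
    folds = np.asarray(fold_changes, dtype=float)
    if folds.shape != (n_genes, n_stages):
        raise ValueError(f"fold_changes must be {n_genes}x{n_stages}")
    if (folds <= 0).any():
        raise ValueError("fold changes must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    folds = folds.copy()
    folds[:, 0] = 1.0  # calibrator stage fixed to fold 1
    stages = [f"DAF{1 + 4 * i}" for i in range(n_stages)]
    rows = []
    for g in range(n_genes):
        gid = f"gene{g + 1}"
        grng = _rng(seed, "ct", gid)
        base_ct = 24.0 + float(grng.uniform(-2.0, 2.0))
        for s, stage in enumerate(stages):
            for r in range(1, replicates + 1):
                noise_t = float(grng.normal(0.0, noise_sd)) if noise_sd else 0.0
                noise_r = float(grng.normal(0.0, noise_sd)) if noise_sd else 0.0
                rows.append(
                    {
                        "gene_id": gid,
                        "sample_id": stage,
                        "replicate": r,
                        "ct_target": base_ct - float(np.log2(folds[g, s])) + noise_t,
                        "ct_reference": ref_ct + noise_r,
                    }
                )
    truth = pd.DataFrame(
        folds, index=[f"gene{g + 1}" for g in range(n_genes)], columns=stages
    )
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# family assembly

def generate_family(config: FamilySimConfig) -> SyntheticFamily:
    """Generate the full synthetic family: genome, gene models, proteins
    and the ground-truth table. Deterministic under ``config.seed``."""
    seed = config.seed

    # deterministic label assignment (largest-remainder apportionment)
    sub_counts = _apportion(config.n_genes, config.subfamily_mix)
    labels: list[tuple[str, str]] = []
    for sub in ("ENODL", "SCL", "UCL", "PLCL"):
        cnt = sub_counts.get(sub, 0)
        if cnt == 0:
            continue
        for t, k in sorted(_restricted_type_counts(sub, cnt, config.type_mix).items()):
            labels.extend([(sub, t)] * k)

    genes: list[GeneModel] = []
    proteins: dict[str, str] = {}
    truth: dict[str, GeneTruth] = {}
    pending: dict[str, dict] = {}  # gene_id -> locus pieces awaiting placement

    lo, hi = config.cds_length_range
    for i, (sub, type_) in enumerate(labels):
        gid = f"g{i + 1:03d}"
        grng = _rng(seed, "gene", gid)
        target_len = int(grng.integers(lo, hi + 1))
        protein, spans = _build_protein(grng, sub, type_, target_len)
        cds = _reverse_translate(protein, grng, config.codon_bias_strength)
        cds += "TAA"
        prng = _rng(seed, "promoter", gid)
        promoter, positions, counts = _build_promoter(
            prng, config.element_dictionary, config.planted_elements
        )
        strand = "+" if _rng(seed, "strand", gid).random() < 0.5 else "-"
        chrom = f"chr{(i % config.n_chromosomes) + 1:02d}"
        pending[gid] = {
            "chrom": chrom,
            "strand": strand,
            "cds": cds,
            "promoter": promoter,
        }
        proteins[gid] = protein
        truth[gid] = GeneTruth(
            gene_id=gid,
            chromosome=chrom,
            strand=strand,
            subfamily=sub,
            type=type_,
            sp=spans["sp"],
            plcd_spans=spans["plcd"],
            ligand_sets=spans["ligands"],
            alr=spans["alr"],
            gas=spans["gas"],
            planted_positions=positions,
            expected_element_counts=counts,
        )

    # duplicate pairs with controlled divergence (tandem neighbours)
    from .selection import ng86_sites  # local import avoids a cycle at load

    base_ids = [f"g{i + 1:03d}" for i in range(len(labels))]
    order: dict[str, list[str]] = {
        f"chr{c + 1:02d}": [] for c in range(config.n_chromosomes)
    }
    for gid in base_ids:
        order[pending[gid]["chrom"]].append(gid)
    for j, (ps_t, pn_t) in enumerate(config.pair_divergence):
        partner = base_ids[j % len(base_ids)]
        dup_id = f"{partner}d"
        t = truth[partner]
        cds = pending[partner]["cds"]
        S, N = ng86_sites(cds)
        syn_n = max(0, round(ps_t * S))
        nonsyn_n = max(0, round(pn_t * N))
        # nonsynonymous changes only in linker/pad codons, never creating
        # His/Cys/Met/Gln or P/A/S/T, so planted domain truth stays valid
        protein = proteins[partner]
        domain_res: set[int] = set()
        for span in [t.sp, t.alr, t.gas] + t.plcd_spans:
            if span:
                domain_res.update(range(span[0], span[1] + 1))
        domain_res.add(1)  # keep the initiator Met
        allowed = {k for k in range(len(protein)) if (k + 1) not in domain_res}
        dup_seed = int(_rng(seed, "pair", partner).integers(2**31))
        mutated, log = mutate_pair(
            cds,
            syn_n,
            nonsyn_n,
            seed=dup_seed,
            allowed_codons=allowed,
            forbidden_residues=set("HCMQPAST"),
        )
        dup_protein = translate(mutated)
        prng = _rng(seed, "promoter", dup_id)
        promoter, positions, counts = _build_promoter(
            prng, config.element_dictionary, config.planted_elements
        )
        pending[dup_id] = {
            "chrom": t.chromosome,
            "strand": pending[partner]["strand"],
            "cds": mutated,
            "promoter": promoter,
        }
        proteins[dup_id] = dup_protein
        truth[dup_id] = GeneTruth(
            gene_id=dup_id,
            chromosome=t.chromosome,
            strand=pending[partner]["strand"],
            subfamily=t.subfamily,
            type=t.type,
            sp=t.sp,
            plcd_spans=list(t.plcd_spans),
            ligand_sets=list(t.ligand_sets),
            alr=t.alr,
            gas=t.gas,
            planted_positions=positions,
            expected_element_counts=counts,
            partner=partner,
            syn_changes=len([e for e in log if e["category"] == "synonymous"]),
            nonsyn_changes=len([e for e in log if e["category"] == "nonsynonymous"]),
        )
        truth[partner].partner = dup_id
        truth[partner].syn_changes = truth[dup_id].syn_changes
        truth[partner].nonsyn_changes = truth[dup_id].nonsyn_changes
        # place the duplicate immediately after its partner
        idx = order[t.chromosome].index(partner)
        order[t.chromosome].insert(idx + 1, dup_id)

    # assemble chromosomes locus by locus; independent loci are separated
    # by 20-35 kb intergenic spacers while a duplicate stays right after
    # its partner, so tandem pairs are positionally distinguishable
    genome: dict[str, str] = {}
    for chrom, gids in order.items():
        parts: list[str] = []
        offset = 0
        for gid in gids:
            info = pending[gid]
            lrng = _rng(seed, "locus", gid)
            is_duplicate = truth[gid].partner is not None and gid.endswith("d")
            if parts and not is_duplicate:
                spacer = _choice_str(lrng, BASES, 20_000 + int(lrng.integers(15_000)))
                parts.append(spacer)
                offset += len(spacer)
            pad5 = _choice_str(lrng, BASES, LOCUS_PAD)
            pad3 = _choice_str(lrng, BASES, LOCUS_PAD)
            cds, promoter = info["cds"], info["promoter"]
            if info["strand"] == "+":
                locus = pad5 + promoter + cds + pad3
                start = offset + LOCUS_PAD + PROMOTER_LEN + 1
                end = start + len(cds) - 1
            else:
                locus = pad5 + reverse_complement(cds) + reverse_complement(promoter) + pad3
                start = offset + LOCUS_PAD + 1
                end = start + len(cds) - 1
            parts.append(locus)
            genes.append(
                GeneModel(gid, chrom, start, end, info["strand"], cds=cds)
            )
            offset += len(locus)
        genome[chrom] = "".join(parts) if parts else _choice_str(
            _rng(seed, "chrom", chrom), BASES, 1000
        )
    genes.sort(key=lambda g: (g.chromosome, g.start))
    return SyntheticFamily(
        genome=genome, genes=genes, proteins=proteins, truth=truth, config=config
    )
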