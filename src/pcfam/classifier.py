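"""Phytocyanin domain detection and subfamily / type / AGP classification.

The family is defined by the plastocyanin-like cupredoxin domain (PLCD)
carrying the copper-ligand set His-Cys-His-(Met|Gln), optionally combined
with an N-terminal signal peptide (SP), a Pro/Ala/Ser/Thr-rich
arabinogalactan-protein-like region (ALR), and a C-terminal GPI anchor
signal (GAS).

Decision rules
--------------
subfamily: no complete ligand set -> ENODL; complete set ending in Q ->
SCL; ending in M with ALR -> UCL, without ALR -> PLCL.

type (domain-architecture lookup; PLCD count regardless of completeness):

    ====  ===  ======  ===  ===
    type  SP   #PLCD   ALR  GAS
    ====  ===  ======  ===  ===
    I     yes  2       yes  yes
    II    yes  1       yes  yes
    III   yes  1       yes  no
    IV    yes  1       no   no
    V     yes  1       no   yes
    VI    no   1       yes  yes
    VII   no   2       yes  yes
    VIII  no   1       no   no
    ====  ===  ======  ===  ===

Any other combination is UNCLASSIFIED. Types VI and VII are disambiguated
by PLCD count (single vs double) — the only assignment consistent with all
architecture constraints; see docs/methods.md.

AGP class: no ALR -> non_AGP; types I, II -> typical_AGP; types III, VI,
VII -> atypical_AGP; chimeric AGP = SP and ALR both present.

The detectors are transparent heuristics with configurable thresholds;
parity with the external predictor servers used in the original study
design is explicitly not claimed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .properties import KYTE_DOOLITTLE
from .sequence_io import GeneModel, ProteinSequence

__all__ = [
    "Span",
    "DetectorConfig",
    "DomainAnnotation",
    "FamilyAnnotation",
    "detect_signal_peptide",
    "detect_plcd",
    "detect_alr",
    "detect_gas",
    "find_nglyc_sites",
    "assign_subfamily",
    "assign_type",
    "assign_agp_class",
    "annotate",
    "classify",
    "read_annotation_table",
    "write_annotation_table",
]

Span = tuple[int, int]  # 1-based inclusive residue interval

SUBFAMILIES = ("UCL", "SCL", "PLCL", "ENODL")
TYPES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: (sp, n_plcd, alr, gas) -> type
_TYPE_TABLE: dict[tuple[bool, int, bool, bool], str] = {
    (True, 2, True, True): "I",
    (True, 1, True, True): "II",
    (True, 1, True, False): "III",
    (True, 1, False, False): "IV",
    (True, 1, False, True): "V",
    (False, 1, True, True): "VI",
    (False, 2, True, True): "VII",
    (False, 1, False, False): "VIII",
}


@dataclass
class DetectorConfig:
    """Tunable thresholds of the heuristic domain detectors."""

    sp_window: int = 8
    sp_hydropathy: float = 1.6
    sp_search_end: int = 25
    plcd_h_c_gap: tuple[int, int] = (20, 90)
    plcd_c_h_gap: tuple[int, int] = (2, 20)
    plcd_h_z_gap: tuple[int, int] = (2, 20)
    alr_window: int = 20
    alr_past_fraction: float = 0.5
    gas_tail_len: int = 12
    gas_tail_hydropathy: float = 1.5
    gas_omega_range: tuple[int, int] = (15, 30)
    gas_omega_residues: str = "GASNDC"


@dataclass
class LigandSet:
    """The four copper-ligand slots of one PLCD, ordered H < C < H < Z."""

    h1: tuple[str, int] | None
    c: tuple[str, int] | None
    h2: tuple[str, int] | None
    z: tuple[str, int] | None
    complete: bool


@dataclass
class DomainAnnotation:
    protein_id: str
    length: int
    sp: Span | None = None
    plcd_spans: list[Span] = field(default_factory=list)
    ligand_sets: list[LigandSet] = field(default_factory=list)
    disulfide_cys: list[int] = field(default_factory=list)
    alr: Span | None = None
    gas: Span | None = None
    nglyc_sites: list[int] = field(default_factory=list)

    @property
    def n_plcd(self) -> int:
        return len(self.plcd_spans)

    def has_complete_ligand_set(self) -> bool:
        return any(s.complete for s in self.ligand_sets)


@dataclass
class FamilyAnnotation:
    protein_id: str
    subfamily: str  # UCL/SCL/PLCL/ENODL, or NON_PC for PLCD-free proteins
    type: str
    agp_class: str
    chimeric_agp: bool
    assigned_name: str


def detect_signal_peptide(
    p: ProteinSequence, cfg: DetectorConfig | None = None
) -> Span | None:
    """N-terminal signal peptide: initial Met plus a hydrophobic core.

    Reported iff residue 1 is M and some ``sp_window``-residue window
    starting within residues 2..``sp_search_end`` has mean Kyte-Doolittle
    >= ``sp_hydropathy``. The span runs to the best window's end + 5
    (nominal cleavage region).
    """
    cfg = cfg or DetectorConfig()
    seq = p.residues
    if len(seq) < 30 or seq[0] != "M":
        return None
    best_score, best_end = None, None
    for start in range(2, min(cfg.sp_search_end, len(seq) - cfg.sp_window) + 1):
        window = seq[start - 1 : start - 1 + cfg.sp_window]
        score = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in window) / cfg.sp_window
        if score >= cfg.sp_hydropathy and (best_score is None or score > best_score):
            best_score, best_end = score, start + cfg.sp_window - 1
    if best_end is None:
        return None
    return (1, min(best_end + 5, len(seq)))


def _plcd_regex(cfg: DetectorConfig) -> re.Pattern[str]:
    (a, b), (c, d), (e, f) = cfg.plcd_h_c_gap, cfg.plcd_c_h_gap, cfg.plcd_h_z_gap
    return re.compile(
        rf"H.{{{a},{b}}}?C.{{{c},{d}}}?H.{{{e},{f}}}?[MQ]"
    )


def detect_plcd(
    p: ProteinSequence, cfg: DetectorConfig | None = None
) -> list[tuple[Span, LigandSet]]:
    """Plastocyanin-like domains: complete copper sites, then incomplete ones.

    A complete site matches H x(20,90) C x(2,20) H x(2,20) [M|Q]
    (leftmost non-overlapping, non-greedy spacings). An incomplete
    (ENODL-type) site is a remaining region with the disulfide Cys
    scaffold C x(2,60) C plus at least two ligand-like residues (His, or
    a trailing M/Q) but no full pattern.
    """
    cfg = cfg or DetectorConfig()
    seq = p.residues
    results: list[tuple[Span, LigandSet]] = []
    occupied: list[Span] = []
    for m in _plcd_regex(cfg).finditer(seq):
        s, e = m.start() + 1, m.end()
        h1 = m.start() + 1
        # recover internal ligand positions from the match itself
        sub = m.group(0)
        c_off = sub.index("C", 1)
        h2_off = sub.index("H", c_off + 1)
        z_off = len(sub) - 1
        ligand = LigandSet(
            h1=("H", h1),
            c=("C", s + c_off - 1 + 1),
            h2=("H", s + h2_off),
            z=(sub[z_off], e),
            complete=True,
        )
        results.append(((s, e), ligand))
        occupied.append((s, e))

    # incomplete sites: Cys scaffold outside complete spans
    scaffold = re.compile(r"C.{2,60}?C")
    pos = 0
    while True:
        m = scaffold.search(seq, pos)
        if m is None:
            break
        s, e = m.start() + 1, m.end()
        if any(not (e < os or s > oe) for os, oe in occupied):
            pos = m.start() + 1  # slide past an occupied start, keep looking
            continue
        pos = m.end()
        # ~70-residue window around the scaffold keeps neighbouring
        # incomplete domains from swallowing each other
        win_lo = max(1, s - 40)
        win_hi = min(len(seq), e + 20)
        window = seq[win_lo - 1 : win_hi]
        n_his = window.count("H")
        tail = seq[e : min(len(seq), e + cfg.plcd_h_z_gap[1])]
        n_ligandish = n_his + (1 if ("M" in tail or "Q" in tail) else 0)
        if n_ligandish >= 2:
            h_positions = [win_lo + i for i, ch in enumerate(window) if ch == "H"]
            ligand = LigandSet(
                h1=("H", h_positions[0]) if h_positions else None,
                c=("C", e),
                h2=("H", h_positions[1]) if len(h_positions) > 1 else None,
                z=None,
                complete=False,
            )
            results.append(((win_lo, win_hi), ligand))
            occupied.append((win_lo, win_hi))
    results.sort(key=lambda r: r[0][0])
    return results


def detect_alr(
    p: ProteinSequence, excluded: list[Span], cfg: DetectorConfig | None = None
) -> Span | None:
    """Arabinogalactan-protein-like region: longest merged run of
    ``alr_window``-residue windows with >= ``alr_past_fraction`` P/A/S/T,
    not overlapping the excluded (SP/PLCD/GAS) spans."""
    cfg = cfg or DetectorConfig()
    seq = p.residues
    w = cfg.alr_window
    if len(seq) < w:
        return None
    past = [1 if a in "PAST" else 0 for a in seq]
    prefix = [0]
    for v in past:
        prefix.append(prefix[-1] + v)

    def overlaps_excluded(s: int, e: int) -> bool:
        return any(not (e < xs or s > xe) for xs, xe in excluded)

    good: list[Span] = []
    for start in range(1, len(seq) - w + 2):
        end = start + w - 1
        frac = (prefix[end] - prefix[start - 1]) / w
        if frac >= cfg.alr_past_fraction and not overlaps_excluded(start, end):
            good.append((start, end))
    if not good:
        return None
    # merge overlapping/adjacent windows into runs, keep the longest
    runs: list[list[int]] = []
    for s, e in good:
        if runs and s <= runs[-1][1] + 1:
            runs[-1][1] = max(runs[-1][1], e)
        else:
            runs.append([s, e])
    best = max(runs, key=lambda r: r[1] - r[0])
    if best[1] - best[0] + 1 < w:
        return None
    return (best[0], best[1])


def detect_gas(
    p: ProteinSequence, cfg: DetectorConfig | None = None
) -> Span | None:
    """GPI anchor signal: hydrophobic C-terminal tail plus a small omega
    candidate 15-30 residues from the terminus; span omega..terminus."""
    cfg = cfg or DetectorConfig()
    seq = p.residues
    if len(seq) < 40:
        return None
    tail = seq[-cfg.gas_tail_len :]
    mean_kd = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in tail) / len(tail)
    if mean_kd < cfg.gas_tail_hydropathy:
        return None
    L = len(seq)
    lo, hi = cfg.gas_omega_range
    for dist in range(lo, hi + 1):  # distance from C-terminus, 1-based
        pos = L - dist + 1
        if pos >= 1 and seq[pos - 1] in cfg.gas_omega_residues:
            return (pos, L)
    return None


_NGLYC = re.compile(r"(?=(N[^P][ST]))")


def find_nglyc_sites(p: ProteinSequence) -> list[int]:
    """1-based positions of N-glycosylation sequons N-X(!=P)-[S/T]."""
    return [m.start() + 1 for m in _NGLYC.finditer(p.residues)]


def assign_subfamily(d: DomainAnnotation) -> str:
    """Copper-ligand rule: ENODL (incomplete site), SCL (Z = Gln), then
    UCL vs PLCL (Z = Met, split on ALR presence)."""
    if d.n_plcd == 0:
        raise ValueError(f"{d.protein_id}: no PLCD — not a phytocyanin")
    complete = [s for s in d.ligand_sets if s.complete]
    if not complete:
        return "ENODL"
    if any(s.z and s.z[0] == "Q" for s in complete):
        return "SCL"
    return "UCL" if d.alr is not None else "PLCL"


def assign_type(d: DomainAnnotation) -> str:
    if d.n_plcd == 0:
        raise ValueError(f"{d.protein_id}: no PLCD — not a phytocyanin")
    key = (d.sp is not None, min(d.n_plcd, 3), d.alr is not None, d.gas is not None)
    return _TYPE_TABLE.get(key, "UNCLASSIFIED")


def assign_agp_class(d: DomainAnnotation, t: str) -> tuple[str, bool]:
    chimeric = d.sp is not None and d.alr is not None
    if d.alr is None:
        return "non_AGP", chimeric
    if t in ("I", "II"):
        return "typical_AGP", chimeric
    if t in ("III", "VI", "VII"):
        return "atypical_AGP", chimeric
    return "non_AGP", chimeric


def annotate(p: ProteinSequence, cfg: DetectorConfig | None = None) -> DomainAnnotation:
    """Run all heuristic detectors on one protein."""
    cfg = cfg or DetectorConfig()
    sp = detect_signal_peptide(p, cfg)
    plcds = detect_plcd(p, cfg)
    gas = detect_gas(p, cfg)
    excluded = [s for s, _ in plcds]
    if sp:
        excluded.append(sp)
    if gas:
        excluded.append(gas)
    alr = detect_alr(p, excluded, cfg)
    cys = sorted({ls.c[1] for _, ls in plcds if ls.c})
    return DomainAnnotation(
        protein_id=p.protein_id,
        length=len(p),
        sp=sp,
        plcd_spans=[s for s, _ in plcds],
        ligand_sets=[ls for _, ls in plcds],
        disulfide_cys=cys,
        alr=alr,
        gas=gas,
        nglyc_sites=find_nglyc_sites(p),
    )


def classify(
    proteins: dict[str, str],
    genes: list[GeneModel],
    mode: str = "heuristic_scan",
    annotations: dict[str, DomainAnnotation] | None = None,
    cfg: DetectorConfig | None = None,
    name_prefix: str = "",
) -> list[FamilyAnnotation]:
    """Classify every protein and assign chromosome-ordered family names.

    ``truth_annotation`` mode applies the decision rules to a supplied
    annotation table; ``heuristic_scan`` runs the detectors. Members are
    named Subfamily+counter in (chromosome, start) order within each
    subfamily; PLCD-free proteins are reported as NON_PC, never dropped.
    """
    if mode not in ("truth_annotation", "heuristic_scan"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "truth_annotation" and annotations is None:
        raise ValueError("truth_annotation mode requires an annotation table")
    gene_order = {
        g.gene_id: (g.chromosome, g.start)
        for g in genes
    }
    results: dict[str, FamilyAnnotation] = {}
    for pid, seq in proteins.items():
        if mode == "truth_annotation":
            d = annotations.get(pid)
            if d is None:
                raise KeyError(f"no annotation for protein {pid}")
        else:
            d = annotate(ProteinSequence(pid, seq), cfg)
        if d.n_plcd == 0:
            results[pid] = FamilyAnnotation(
                pid, "NON_PC", "UNCLASSIFIED", "non_AGP", False, ""
            )
            continue
        sub = assign_subfamily(d)
        t = assign_type(d)
        agp, chimeric = assign_agp_class(d, t)
        results[pid] = FamilyAnnotation(pid, sub, t, agp, chimeric, "")
    # chromosome-ordered naming within each subfamily
    for sub in SUBFAMILIES:
        members = [
            pid
            for pid, fa in results.items()
            if fa.subfamily == sub and pid in gene_order
        ]
        members.sort(key=lambda pid: gene_order[pid])
        for i, pid in enumerate(members, start=1):
            results[pid].assigned_name = f"{name_prefix}{sub}{i}"
    return list(results.values())


# ---------------------------------------------------------------------------
# annotation-table round trip (truth mode interchange format)

def _span_str(span: Span | None) -> str:
    return f"{span[0]}-{span[1]}" if span else "."


def _parse_span(s: str) -> Span | None:
    if s in (".", ""):
        return None
    a, b = s.split("-")
    return (int(a), int(b))


def write_annotation_table(path: str | Path, annotations: list[DomainAnnotation]) -> None:
    rows = []
    for d in annotations:
        ligands = ";".join(
            ",".join(
                f"{slot[0]}{slot[1]}" if slot else "."
                for slot in (ls.h1, ls.c, ls.h2, ls.z)
            )
            + ("*" if ls.complete else "")
            for ls in d.ligand_sets
        )
        rows.append(
            {
                "protein_id": d.protein_id,
                "length": d.length,
                "sp": _span_str(d.sp),
                "plcd_spans": ";".join(_span_str(s) for s in d.plcd_spans) or ".",
                "ligand_sets": ligands or ".",
                "alr": _span_str(d.alr),
                "gas": _span_str(d.gas),
                "nglyc_sites": ";".join(map(str, d.nglyc_sites)) or ".",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_slot(s: str) -> tuple[str, int] | None:
    if s == ".":
        return None
    return (s[0], int(s[1:]))


def read_annotation_table(path: str | Path) -> dict[str, DomainAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(".")
    out: dict[str, DomainAnnotation] = {}
    for _, row in df.iterrows():
        spans = (
            [(_parse_span(s)) for s in row["plcd_spans"].split(";")]
            if row["plcd_spans"] != "."
            else []
        )
        ligand_sets = []
        if row["ligand_sets"] != ".":
            for chunk in row["ligand_sets"].split(";"):
                complete = chunk.endswith("*")
                chunk = chunk.rstrip("*")
                slots = [_parse_slot(s) for s in chunk.split(",")]
                ligand_sets.append(LigandSet(*slots, complete=complete))
        out[row["protein_id"]] = DomainAnnotation(
            protein_id=row["protein_id"],
            length=int(row["length"]),
            sp=_parse_span(row["sp"]),
            plcd_spans=[s for s in spans if s],
            ligand_sets=ligand_sets,
            alr=_parse_span(row["alr"]),
            gas=_parse_span(row["gas"]),
            nglyc_sites=(
                [int(x) for x in row["nglyc_sites"].split(";")]
                if row["nglyc_sites"] != "."
                else []
            ),
        )
    return out
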