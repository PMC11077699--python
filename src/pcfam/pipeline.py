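"""End-to-end characterization pipeline with per-stage TSVs and manifests.

Stage order mirrors the analysis flow: identify/classify -> protein
properties -> codon bias -> Ka/Ks + tandem clusters -> promoters ->
expression. Every stage writes a TSV and records its row count and output
hash in ``manifest.json``; manifests contain no timestamps so reruns with
the same config and inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import codon as codon_mod
from . import classifier as clf
from . import expression as expr
from . import promoter as prom
from . import properties as props
from . import selection as sel
from .sequence_io import extract_promoter, read_fasta, read_gff3, translate

__version__ = "0.1.0"

__all__ = ["RunConfig", "run_pipeline", "summarize_family"]


@dataclass
class RunConfig:
    genome_fasta: str
    gff3: str
    outdir: str
    mode: str = "heuristic_scan"
    annotation_tsv: str | None = None
    pairs_tsv: str | None = None
    ct_tsv: str | None = None
    anthocyanin_tsv: str | None = None
    calibrator: str = "DAF1"
    promoter_length: int = 2000
    element_tsv: str | None = None
    tandem_max_separation: int = 250_000
    tandem_max_intervening: int = 5
    cai_reference_tsv: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.promoter_length <= 0:
            raise ValueError("promoter length must be positive")
        required = {"genome_fasta": self.genome_fasta, "gff3": self.gff3}
        optional = {
            "annotation_tsv": self.annotation_tsv,
            "pairs_tsv": self.pairs_tsv,
            "ct_tsv": self.ct_tsv,
            "anthocyanin_tsv": self.anthocyanin_tsv,
            "element_tsv": self.element_tsv,
            "cai_reference_tsv": self.cai_reference_tsv,
        }
        for name, path in required.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        for name, path in optional.items():
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path} does not exist")
        if self.mode == "truth_annotation" and self.annotation_tsv is None:
            raise ValueError("truth_annotation mode requires annotation_tsv")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()


def _extract_cds(genome, genes):
    from ._genetic_code import reverse_complement

    for g in genes:
        raw = genome[g.chromosome][g.start - 1 : g.end]
        g.cds = raw if g.strand == "+" else reverse_complement(raw)
    return genes


def run_pipeline(config: RunConfig, log=sys.stderr) -> dict:
    """Execute all stages; returns the manifest dict (also written to
    ``outdir/manifest.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "pcfam",
        "version": __version__,
        "config_hash": _config_hash(config),
        "stages": {},
    }

    def stage_done(name: str, path: Path, rows: int) -> None:
        manifest["stages"][name] = {
            "output": path.name,
            "rows": rows,
            "sha256": _sha256(path),
        }
        print(f"[pcfam] stage {name}: {rows} rows -> {path}", file=log)

    genome = read_fasta(config.genome_fasta)
    genes = read_gff3(config.gff3, feature="gene")
    _extract_cds(genome, genes)
    proteins = {g.gene_id: translate(g.cds) for g in genes}

    # --- classification -----------------------------------------------
    annotations = None
    if config.annotation_tsv:
        annotations = clf.read_annotation_table(config.annotation_tsv)
    family = clf.classify(
        proteins, genes, mode=config.mode, annotations=annotations
    )
    fam_df = pd.DataFrame([vars(f) for f in family])
    path = outdir / "classification.tsv"
    fam_df.to_csv(path, sep="\t", index=False)
    stage_done("classification", path, len(fam_df))
    member_ids = {f.protein_id for f in family if f.subfamily != "NON_PC"}

    # --- physicochemical properties ------------------------------------
    prop_df = props.profile_table(proteins)
    path = outdir / "properties.tsv"
    prop_df.to_csv(path, sep="\t", index=False)
    stage_done("properties", path, len(prop_df))

    # --- codon usage ----------------------------------------------------
    if config.cai_reference_tsv:
        ref = pd.read_csv(config.cai_reference_tsv, sep="\t")
        weights = dict(zip(ref.codon, ref.weight))
    else:
        # default reference: the analyzed family itself
        pooled = codon_mod.count_codons("".join(g.cds for g in genes))
        weights = codon_mod.cai_weights(pooled)
    base_profiles = [codon_mod.profile_gene(g.gene_id, g.cds) for g in genes]
    optimal = codon_mod.optimal_codons(base_profiles)
    profiles = [
        codon_mod.profile_gene(g.gene_id, g.cds, weights, optimal) for g in genes
    ]
    codon_df = codon_mod.profile_table(profiles)
    path = outdir / "codon_usage.tsv"
    codon_df.to_csv(path, sep="\t", index=False)
    stage_done("codon_usage", path, len(codon_df))

    rscu_df = codon_mod.pooled_rscu_table(profiles)
    path = outdir / "pooled_rscu.tsv"
    rscu_df.to_csv(path, sep="\t", index=False)
    stage_done("pooled_rscu", path, len(rscu_df))

    corr = codon_mod.index_correlations(profiles)
    path = outdir / "index_correlations.tsv"
    corr.to_csv(path, sep="\t")
    stage_done("index_correlations", path, len(corr))

    # --- selection ------------------------------------------------------
    cds_by_id = {g.gene_id: g.cds for g in genes}
    if config.pairs_tsv:
        pairs = pd.read_csv(config.pairs_tsv, sep="\t")
        rows = []
        for _, pr in pairs.iterrows():
            res = sel.kaks(
                cds_by_id[pr.gene_a], cds_by_id[pr.gene_b], ids=(pr.gene_a, pr.gene_b)
            )
            d = vars(res).copy()
            d["gene_a"], d["gene_b"] = d.pop("pair")
            rows.append(d)
        kaks_df = pd.DataFrame(rows)
        path = outdir / "kaks.tsv"
        kaks_df.to_csv(path, sep="\t", index=False)
        stage_done("kaks", path, len(kaks_df))
    else:
        print("[pcfam] stage kaks skipped: no pairs table", file=log)

    clusters = sel.tandem_clusters(
        genes,
        member_ids,
        max_separation=config.tandem_max_separation,
        max_intervening=config.tandem_max_intervening,
    )
    cl_df = pd.DataFrame(
        [
            {
                "chromosome": c.chromosome,
                "members": ",".join(c.members),
                "n_members": len(c.members),
                "span_bp": c.span,
            }
            for c in clusters
        ],
        columns=["chromosome", "members", "n_members", "span_bp"],
    )
    path = outdir / "tandem_clusters.tsv"
    cl_df.to_csv(path, sep="\t", index=False)
    stage_done("tandem_clusters", path, len(cl_df))

    # --- promoters ------------------------------------------------------
    elements = prom.load_element_dictionary(config.element_tsv)
    promoters = {}
    for g in genes:
        seq, _trunc = extract_promoter(g, genome, config.promoter_length)
        if seq:
            promoters[g.gene_id] = seq
    hits = prom.scan_promoters(promoters, elements)
    hit_rows = [vars(h) for hs in hits.values() for h in hs]
    hits_df = pd.DataFrame(
        hit_rows, columns=["gene_id", "element", "start", "end", "strand", "matched"]
    )
    path = outdir / "promoter_hits.tsv"
    hits_df.to_csv(path, sep="\t", index=False)
    stage_done("promoter_hits", path, len(hits_df))

    summary = prom.summarize_counts(hits, elements)
    path = outdir / "promoter_summary.tsv"
    summary.to_csv(path, sep="\t")
    stage_done("promoter_summary", path, len(summary))

    # --- expression (optional) -----------------------------------------
    if config.ct_tsv:
        ct = pd.read_csv(config.ct_tsv, sep="\t")
        folds = expr.delta_delta_ct(ct, calibrator=config.calibrator)
        path = outdir / "expression_folds.tsv"
        folds.to_csv(path, sep="\t")
        stage_done("expression_folds", path, len(folds))
    else:
        print("[pcfam] stage expression skipped: no Ct table", file=log)
    if config.anthocyanin_tsv:
        an = pd.read_csv(config.anthocyanin_tsv, sep="\t")
        an_df = expr.anthocyanin_table(an)
        path = outdir / "anthocyanin.tsv"
        an_df.to_csv(path, sep="\t", index=False)
        stage_done("anthocyanin", path, len(an_df))

    # --- summary --------------------------------------------------------
    summary_df = summarize_family(fam_df, genes, cl_df, hits, elements)
    path = outdir / "family_summary.tsv"
    summary_df.to_csv(path, sep="\t", index=False)
    stage_done("family_summary", path, len(summary_df))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def summarize_family(
    fam_df: pd.DataFrame,
    genes,
    clusters_df: pd.DataFrame,
    hits: dict,
    elements,
) -> pd.DataFrame:
    """Count table: per subfamily, per type, per chromosome, AGP classes,
    tandem clusters, and genes with >= 1 hit per element category."""
    rows: list[dict] = []
    members = fam_df[fam_df.subfamily != "NON_PC"]
    rows.append({"metric": "n_genes", "key": "total", "value": len(fam_df)})
    rows.append({"metric": "n_family_members", "key": "total", "value": len(members)})
    for sub, n in members.subfamily.value_counts().items():
        rows.append({"metric": "subfamily", "key": sub, "value": int(n)})
    for t, n in members.type.value_counts().items():
        rows.append({"metric": "type", "key": t, "value": int(n)})
    chrom_of = {g.gene_id: g.chromosome for g in genes}
    member_ids = set(members.protein_id)
    chrom_counts: dict[str, int] = {}
    for gid in member_ids:
        c = chrom_of.get(gid)
        if c:
            chrom_counts[c] = chrom_counts.get(c, 0) + 1
    for c in sorted(chrom_counts):
        rows.append({"metric": "chromosome", "key": c, "value": chrom_counts[c]})
    for agp, n in members.agp_class.value_counts().items():
        rows.append({"metric": "agp_class", "key": agp, "value": int(n)})
    rows.append(
        {"metric": "chimeric_agp", "key": "total", "value": int(members.chimeric_agp.sum())}
    )
    rows.append({"metric": "tandem_clusters", "key": "total", "value": len(clusters_df)})
    categories = sorted({el.category for el in elements})
    for cat in categories:
        names = {el.name for el in elements if el.category == cat}
        n_genes = sum(
            1 for hs in hits.values() if any(h.element in names for h in hs)
        )
        rows.append({"metric": "genes_with_element_category", "key": cat, "value": n_genes})
    meja = sum(
        1
        for hs in hits.values()
        if any(h.element in prom.MEJA_ELEMENTS for h in hs)
    )
    rows.append({"metric": "genes_with_meja_element", "key": "total", "value": meja})
    return pd.DataFrame(rows)
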