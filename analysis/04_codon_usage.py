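"""Codon-usage bias battery over the family CDS set.

Computes per-gene RSCU/ENC/CAI/CBI/Fop and base composition, calls the
family's optimal codons (pooled RSCU > 1), and writes the index
correlation matrix to results/codon_correlations.tsv.
"""

from _common import get_family, results_dir
from pcfam import codon as C

fam = get_family()
cds = {g.gene_id: g.cds for g in fam.genes}

pooled = C.count_codons("".join(cds.values()))
weights = C.cai_weights(pooled)
base = [C.profile_gene(g, s) for g, s in cds.items()]
optimal = C.optimal_codons(base)
profiles = [C.profile_gene(g, s, weights, optimal) for g, s in cds.items()]

table = C.profile_table(profiles)
print(f"{len(profiles)} genes profiled")
print(f"ENC range: {table.enc.min():.2f} - {table.enc.max():.2f}")
print(f"CAI range: {table.cai.min():.3f} - {table.cai.max():.3f}")
print(f"Optimal codons (pooled RSCU > 1): {len(optimal)}")

# the generator's designated codons should dominate the optimal set
from pcfam.synthetic import DESIGNATED_CODONS
from pcfam._genetic_code import AA_TO_CODONS

designated = {
    DESIGNATED_CODONS[aa] for aa, cs in AA_TO_CODONS.items() if len(cs) > 1
}
print(f"Designated-codon overlap: {len(optimal & designated)}/{len(designated)}")

corr = C.index_correlations(profiles)
corr.round(4).to_csv(results_dir() / "codon_correlations.tsv", sep="\t")
C.pooled_rscu_table(profiles).round(4).to_csv(
    results_dir() / "pooled_rscu.tsv", sep="\t", index=False
)
print("Wrote results/codon_correlations.tsv and results/pooled_rscu.tsv")
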