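import numpy as np
import pytest

from pcfam._genetic_code import CODON_TO_AA, codons_of
from pcfam.sequence_io import translate
from pcfam.synthetic import (
    FamilySimConfig,
    generate_ct_table,
    generate_family,
    mutate_pair,
)


class TestConfigValidation:
    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="subfamily_mix"):
            FamilySimConfig(subfamily_mix={"ENODL": 0.5, "SCL": 0.2, "UCL": 0.2, "PLCL": 0.2})

    def test_plcl_requires_alr_free_type(self):
        with pytest.raises(ValueError, match="ALR-free"):
            FamilySimConfig(
                subfamily_mix={"PLCL": 1.0},
                type_mix={"II": 1.0},
            )

    def test_min_cds_length(self):
        with pytest.raises(ValueError, match="120"):
            FamilySimConfig(cds_length_range=(90, 200))

    def test_unknown_planted_element(self):
        with pytest.raises(ValueError, match="not in dictionary"):
            FamilySimConfig(planted_elements=[("NOPE", 1)])


class TestGenerateFamily:
    def test_byte_identical_under_seed(self):
        a = generate_family(FamilySimConfig(n_genes=12, seed=7, pair_divergence=[]))
        b = generate_family(FamilySimConfig(n_genes=12, seed=7, pair_divergence=[]))
        assert a.genome == b.genome
        assert a.proteins == b.proteins
        assert [g.cds for g in a.genes] == [g.cds for g in b.genes]

    def test_scl_only_mix_plants_gln_ligands(self):
        cfg = FamilySimConfig(
            n_genes=8, subfamily_mix={"SCL": 1.0}, seed=3, pair_divergence=[]
        )
        fam = generate_family(cfg)
        for t in fam.truth.values():
            assert t.subfamily == "SCL"
            for ls in t.ligand_sets:
                assert ls.z[0] == "Q"

    def test_planted_gbox_copies_at_truth_positions(self):
        cfg = FamilySimConfig(
            n_genes=4, planted_elements=[("G-box", 3)], seed=5, pair_divergence=[]
        )
        fam = generate_family(cfg)
        from pcfam.promoter import DEFAULT_ELEMENTS, scan_promoter
        from pcfam.sequence_io import extract_promoter

        for g in fam.genes:
            truth = fam.truth[g.gene_id]
            assert len(truth.planted_positions["G-box"]) == 3
            seq, _ = extract_promoter(g, fam.genome, 2000)
            starts = {
                h.start
                for h in scan_promoter(seq, DEFAULT_ELEMENTS)
                if h.element == "G-box"
            }
            assert starts == set(truth.planted_positions["G-box"])

    def test_truth_spans_inside_protein(self, small_family):
        for gid, t in small_family.truth.items():
            L = len(small_family.proteins[gid])
            for span in [t.sp, t.alr, t.gas] + t.plcd_spans:
                if span:
                    assert 1 <= span[0] <= span[1] <= L
            for ls, span in zip(t.ligand_sets, t.plcd_spans):
                for slot in (ls.h1, ls.c, ls.h2, ls.z):
                    if slot:
                        assert span[0] <= slot[1] <= span[1]

    def test_cds_matches_genome_slice_and_protein(self, small_family):
        from pcfam._genetic_code import reverse_complement

        fam = small_family
        for g in fam.genes:
            raw = fam.genome[g.chromosome][g.start - 1 : g.end]
            cds = raw if g.strand == "+" else reverse_complement(raw)
            assert cds == g.cds
            assert translate(cds) == fam.proteins[g.gene_id]

    def test_gene_spacing_at_least_5kb(self, small_family):
        dup_ids = {
            t.gene_id for t in small_family.truth.values()
            if t.partner and t.gene_id.endswith("d")
        }
        by_chrom: dict[str, list] = {}
        for g in small_family.genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for genes in by_chrom.values():
            genes = sorted(genes, key=lambda g: g.start)
            for a, b in zip(genes, genes[1:]):
                assert b.start - a.end >= 5000
                if b.gene_id not in dup_ids:
                    # independent loci carry a wide intergenic spacer
                    assert b.start - a.end >= 20_000

    def test_every_gene_in_truth_exactly_once(self, small_family):
        ids = [g.gene_id for g in small_family.genes]
        assert sorted(ids) == sorted(small_family.truth)
        assert len(set(ids)) == len(ids)

    def test_write_bundle_round_trips(self, tmp_path, small_family):
        from pcfam.sequence_io import read_fasta, read_gff3

        paths = small_family.write(tmp_path / "sim")
        genome = read_fasta(paths["genome"])
        assert genome == small_family.genome
        genes = read_gff3(paths["gff3"])
        assert len(genes) == len(small_family.genes)
        proteins = read_fasta(paths["proteins"])
        assert proteins == small_family.proteins


class TestMutatePair:
    CDS = "ATG" + "GGTGCAAAAGATCTTGTG" * 20

    def test_zero_changes_identity(self):
        out, log = mutate_pair(self.CDS, 0, 0, seed=1)
        assert out == self.CDS and log == []

    def test_fourfold_site_synonymous_change(self):
        cds = "GGG" * 10
        out, log = mutate_pair(cds, 1, 0, seed=2)
        (entry,) = log
        assert entry["category"] == "synonymous"
        assert entry["nt_position"] % 3 == 0  # third codon position
        assert translate(out) == translate(cds)

    def test_log_matches_codon_recount(self):
        for seed in range(5):
            out, log = mutate_pair(self.CDS, 6, 3, seed=seed)
            assert len(log) == 9
            syn = nonsyn = 0
            for ca, cb in zip(codons_of(self.CDS), codons_of(out)):
                if ca == cb:
                    continue
                assert sum(x != y for x, y in zip(ca, cb)) == 1
                if CODON_TO_AA[ca] == CODON_TO_AA[cb]:
                    syn += 1
                else:
                    nonsyn += 1
            assert (syn, nonsyn) == (6, 3)

    def test_changes_at_distinct_codons(self):
        _, log = mutate_pair(self.CDS, 8, 4, seed=3)
        idx = [e["codon_index"] for e in log]
        assert len(idx) == len(set(idx))

    def test_no_stop_codons_created(self):
        for seed in range(5):
            out, _ = mutate_pair(self.CDS, 10, 10, seed=seed)
            translate(out)  # raises on internal stop

    def test_infeasible_request_states_shortfall(self):
        with pytest.raises(ValueError, match="synonymous"):
            mutate_pair("ATGTGG", 3, 0, seed=1)  # Met+Trp: no synonymous site

    def test_forbidden_residues_respected(self):
        out, log = mutate_pair(
            self.CDS, 0, 10, seed=4, forbidden_residues=set("HCMQPAST")
        )
        prot = translate(out)
        for e in log:
            aa = prot[e["codon_index"]]
            assert aa not in set("HCMQPAST")


class TestCtTable:
    def test_noise_free_construction(self):
        folds = np.array([[1.0, 4.0]])
        ct, truth = generate_ct_table(1, 2, folds, noise_sd=0.0, replicates=2, seed=1)
        g = ct[ct.sample_id == "DAF5"]
        cal = ct[ct.sample_id == "DAF1"]
        assert (cal.ct_target.iloc[0] - g.ct_target.iloc[0]) == pytest.approx(2.0)
        assert (ct.ct_reference == 20.0).all()

    def test_nonpositive_fold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            generate_ct_table(1, 2, np.array([[1.0, 0.0]]), seed=1)

    def test_calibrator_forced_to_one(self):
        ct, truth = generate_ct_table(
            2, 3, np.array([[5.0, 2.0, 3.0], [9.0, 1.0, 1.0]]), noise_sd=0.0, seed=2
        )
        assert (truth["DAF1"] == 1.0).all()
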