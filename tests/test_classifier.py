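from itertools import product

import pytest

from pcfam.classifier import (
    DomainAnnotation,
    LigandSet,
    annotate,
    assign_agp_class,
    assign_subfamily,
    assign_type,
    classify,
    detect_alr,
    detect_gas,
    detect_plcd,
    detect_signal_peptide,
    find_nglyc_sites,
    read_annotation_table,
    write_annotation_table,
)
from pcfam.sequence_io import GeneModel, ProteinSequence


def P(seq):
    return ProteinSequence("p", seq)


FILLER40 = "DEKNGR" * 7  # hydrophilic, no H/C/M/Q, no P/A/S/T


def plcd_block(z="M"):
    f = "DEKNGR"
    return "H" + (f * 5) + "C" + (f * 2)[:9] + "C" + f[:5] + "H" + f[:5] + z


class TestSignalPeptide:
    def test_hydrophobic_start_detected(self):
        seq = "M" + "LLLLLLLL" + "DD" + FILLER40 * 3
        span = detect_signal_peptide(P(seq))
        assert span is not None and span[0] == 1

    def test_polar_start_absent(self):
        seq = "M" + "DDDDDDDD" + FILLER40 * 3
        assert detect_signal_peptide(P(seq)) is None

    def test_requires_initial_met(self):
        seq = "K" + "LLLLLLLL" + FILLER40 * 3
        assert detect_signal_peptide(P(seq)) is None


class TestPlcd:
    def test_planted_ucl_pattern_complete_met(self):
        seq = "M" + FILLER40 + plcd_block("M") + FILLER40
        (result,) = detect_plcd(P(seq))
        span, ligands = result
        assert ligands.complete and ligands.z[0] == "M"
        h1, c, h2, z = ligands.h1, ligands.c, ligands.h2, ligands.z
        assert h1[1] < c[1] < h2[1] < z[1]

    def test_planted_scl_pattern_complete_gln(self):
        seq = "M" + FILLER40 + plcd_block("Q") + FILLER40
        (result,) = detect_plcd(P(seq))
        assert result[1].complete and result[1].z[0] == "Q"

    def test_planted_enodl_block_incomplete(self):
        seq = "M" + FILLER40 + plcd_block("A") + FILLER40
        (result,) = detect_plcd(P(seq))
        assert not result[1].complete and result[1].z is None

    def test_two_blocks_reported_in_order(self):
        seq = "M" + FILLER40 + plcd_block("M") + "DEKNGR" * 5 + plcd_block("M") + FILLER40
        results = detect_plcd(P(seq))
        assert len(results) == 2
        assert results[0][0][0] < results[1][0][0]

    def test_two_incomplete_blocks_both_found(self):
        seq = "M" + FILLER40 + plcd_block("A") + "DEKNGR" * 5 + plcd_block("G") + FILLER40
        results = detect_plcd(P(seq))
        assert len(results) == 2
        assert not any(lig.complete for _, lig in results)


class TestAlr:
    def test_past_rich_block_detected(self):
        seq = FILLER40 + ("PAST" * 5 + "DEKNGRDEKN")[:30] + FILLER40
        span = detect_alr(P(seq), excluded=[])
        assert span is not None

    def test_all_leucine_absent(self):
        assert detect_alr(P("L" * 80), excluded=[]) is None

    def test_excluded_span_suppresses_report(self):
        block = "PAST" * 8
        seq = FILLER40 + block + FILLER40
        lo = len(FILLER40) + 1
        hi = lo + len(block) - 1
        assert detect_alr(P(seq), excluded=[(lo, hi)]) is None


class TestGas:
    def test_planted_tail_detected_at_omega(self):
        seq = FILLER40 * 2 + "EKR" + "S" + "EKREKREKR" + "LVIFLVIFLVIF"
        span = detect_gas(P(seq))
        assert span is not None
        assert span[1] == len(seq)
        assert len(seq) - span[0] + 1 == 22  # omega distance from terminus

    def test_hydrophilic_terminus_absent(self):
        assert detect_gas(P(FILLER40 * 3)) is None

    def test_hydrophobic_tail_without_omega_absent(self):
        seq = FILLER40 * 2 + "EKREKREKREKREKREKR" + "LVIFLVIFLVIF"
        assert detect_gas(P(seq)) is None


class TestNglyc:
    @pytest.mark.parametrize(
        "seq,expected",
        [("NGS", [1]), ("NPS", []), ("NGSNGT", [1, 4]), ("KNGSK", [2])],
    )
    def test_sequon_rule(self, seq, expected):
        assert find_nglyc_sites(P(seq)) == expected


def domain(sp=False, n_plcd=1, alr=False, gas=False, z="M", complete=True):
    sets = [
        LigandSet(("H", 10 + 60 * i), ("C", 50 + 60 * i), ("H", 56 + 60 * i),
                  (z, 62 + 60 * i) if complete else None, complete=complete)
        for i in range(n_plcd)
    ]
    return DomainAnnotation(
        protein_id="p",
        length=300,
        sp=(1, 15) if sp else None,
        plcd_spans=[(10 + 60 * i, 63 + 60 * i) for i in range(n_plcd)],
        ligand_sets=sets,
        alr=(200, 230) if alr else None,
        gas=(270, 300) if gas else None,
    )


class TestSubfamilyRules:
    def test_met_ligand_with_alr_is_ucl(self):
        assert assign_subfamily(domain(alr=True, z="M")) == "UCL"

    def test_met_ligand_without_alr_is_plcl(self):
        assert assign_subfamily(domain(alr=False, z="M")) == "PLCL"

    def test_gln_ligand_is_scl(self):
        assert assign_subfamily(domain(alr=True, z="Q")) == "SCL"

    def test_incomplete_site_is_enodl(self):
        assert assign_subfamily(domain(complete=False)) == "ENODL"

    def test_no_plcd_raises(self):
        d = domain()
        d.plcd_spans, d.ligand_sets = [], []
        with pytest.raises(ValueError, match="not a phytocyanin"):
            assign_subfamily(d)


class TestTypeTable:
    CANONICAL = {
        (True, 2, True, True): "I",
        (True, 1, True, True): "II",
        (True, 1, True, False): "III",
        (True, 1, False, False): "IV",
        (True, 1, False, True): "V",
        (False, 1, True, True): "VI",
        (False, 2, True, True): "VII",
        (False, 1, False, False): "VIII",
    }

    def test_exhaustive_architecture_grid(self):
        for sp, n, alr, gas in product([True, False], [1, 2], [True, False], [True, False]):
            t = assign_type(domain(sp=sp, n_plcd=n, alr=alr, gas=gas))
            assert t == self.CANONICAL.get((sp, n, alr, gas), "UNCLASSIFIED")

    def test_completeness_irrelevant_for_type(self):
        # two incomplete PLCDs with SP/ALR/GAS still type I (ENODL case)
        t = assign_type(domain(sp=True, n_plcd=2, alr=True, gas=True, complete=False))
        assert t == "I"


class TestAgpRules:
    @pytest.mark.parametrize(
        "kwargs,expected_class,expected_chimeric",
        [
            (dict(sp=True, n_plcd=1, alr=True, gas=True), "typical_AGP", True),    # II
            (dict(sp=False, n_plcd=1, alr=True, gas=True), "atypical_AGP", False), # VI
            (dict(sp=True, n_plcd=1, alr=False, gas=False), "non_AGP", False),     # IV
            (dict(sp=True, n_plcd=1, alr=True, gas=False), "atypical_AGP", True),  # III
        ],
    )
    def test_rules(self, kwargs, expected_class, expected_chimeric):
        d = domain(**kwargs)
        t = assign_type(d)
        agp, chimeric = assign_agp_class(d, t)
        assert agp == expected_class and chimeric == expected_chimeric


class TestClassify:
    def test_naming_follows_chromosome_order(self):
        seq = "M" + FILLER40 + plcd_block("M") + "DEKNGR" * 4 + "PAST" * 8 + FILLER40
        proteins = {"a": seq, "b": seq}
        genes = [
            GeneModel("b", "chr1", 1000, 2000, "+"),
            GeneModel("a", "chr3", 1000, 2000, "+"),
        ]
        results = {r.protein_id: r for r in classify(proteins, genes)}
        assert results["b"].assigned_name == "UCL1"
        assert results["a"].assigned_name == "UCL2"

    def test_non_pc_reported_not_dropped(self):
        proteins = {"x": "M" + FILLER40 * 4}
        genes = [GeneModel("x", "chr1", 1, 100, "+")]
        (r,) = classify(proteins, genes)
        assert r.subfamily == "NON_PC" and r.assigned_name == ""

    def test_truth_mode_recovers_planted_labels(self, small_family, small_family_annotations):
        fam = small_family
        results = classify(
            fam.proteins, fam.genes, mode="truth_annotation",
            annotations=small_family_annotations,
        )
        by_id = {r.protein_id: r for r in results}
        for gid, t in fam.truth.items():
            assert (by_id[gid].subfamily, by_id[gid].type) == (t.subfamily, t.type)

    def test_heuristic_mode_recovers_planted_labels(self, small_family):
        fam = small_family
        results = classify(fam.proteins, fam.genes, mode="heuristic_scan")
        by_id = {r.protein_id: r for r in results}
        mismatch = sum(
            (by_id[g].subfamily, by_id[g].type) != (t.subfamily, t.type)
            for g, t in fam.truth.items()
        )
        assert mismatch == 0

    def test_subfamily_counts_partition_members(self, small_family):
        results = classify(small_family.proteins, small_family.genes)
        members = [r for r in results if r.subfamily != "NON_PC"]
        by_sub = {}
        for r in members:
            by_sub[r.subfamily] = by_sub.get(r.subfamily, 0) + 1
        assert sum(by_sub.values()) == len(members)
        assert set(by_sub) <= {"UCL", "SCL", "PLCL", "ENODL"}

    def test_ligand_ordering_invariant(self, small_family):
        for gid, seq in small_family.proteins.items():
            ann = annotate(ProteinSequence(gid, seq))
            for ls in ann.ligand_sets:
                pos = [slot[1] for slot in (ls.h1, ls.c, ls.h2, ls.z) if slot]
                assert pos == sorted(pos)

    def test_annotation_table_round_trip(self, tmp_path, small_family_annotations):
        path = tmp_path / "ann.tsv"
        annotations = list(small_family_annotations.values())
        write_annotation_table(path, annotations)
        back = read_annotation_table(path)
        for d in annotations:
            r = back[d.protein_id]
            assert (r.sp, r.alr, r.gas) == (d.sp, d.alr, d.gas)
            assert r.plcd_spans == d.plcd_spans
            assert [ls.complete for ls in r.ligand_sets] == [
                ls.complete for ls in d.ligand_sets
            ]
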