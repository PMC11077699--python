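import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pcfam._genetic_code import AA_TO_CODONS, CODON_TO_AA
from pcfam import codon as C

from .oracles import wright_enc

SENSE = sorted(CODON_TO_AA)

random_counts = st.dictionaries(
    st.sampled_from(SENSE), st.integers(min_value=0, max_value=50), max_size=61
)


def uniform_codon_gene(rng, n):
    return {c: int(x) for c, x in zip(SENSE, np.bincount(rng.integers(0, 61, n), minlength=61))}


class TestRscu:
    def test_alanine_example(self):
        out = C.rscu({"GCT": 3, "GCC": 1})
        assert out["GCT"] == pytest.approx(3.0)
        assert out["GCC"] == pytest.approx(1.0)
        assert out["GCA"] == 0.0 and out["GCG"] == 0.0

    def test_uniform_usage_gives_all_ones(self):
        counts = {c: 4 for c in SENSE}
        assert all(v == pytest.approx(1.0) for v in C.rscu(counts).values())

    def test_single_codon_amino_acids_fixed_at_one(self):
        out = C.rscu({"ATG": 7, "TGG": 3})
        assert out["ATG"] == pytest.approx(1.0)
        assert out["TGG"] == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=60)
    @given(random_counts)
    def test_family_sums_equal_degeneracy(self, counts):
        out = C.rscu(counts)
        for aa, codons in AA_TO_CODONS.items():
            if sum(counts.get(c, 0) for c in codons) == 0:
                continue
            assert sum(out[c] for c in codons) == pytest.approx(len(codons), abs=1e-9)


class TestEnc:
    def test_single_codon_per_amino_acid_gives_20(self):
        counts = {AA_TO_CODONS[aa][0]: 10 for aa in AA_TO_CODONS}
        assert C.enc(counts) == pytest.approx(20.0)

    def test_uniform_long_gene_near_61(self):
        rng = np.random.default_rng(3)
        value = C.enc(uniform_codon_gene(rng, 3000))
        assert 59.0 <= value <= 61.0

    def test_no_synonymous_information_is_missing(self):
        assert math.isnan(C.enc({"ATG": 5, "TGG": 5}))

    def test_matches_direct_wright_restatement(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            counts = uniform_codon_gene(rng, int(rng.integers(100, 2000)))
            mine, ref = C.enc(counts), wright_enc(counts)
            if math.isnan(ref):
                assert math.isnan(mine)
            else:
                assert mine == pytest.approx(ref, abs=1e-9)

    def test_scale_dependence_via_n_only(self):
        counts = {"GCT": 6, "GCC": 2, "GGT": 8, "GGC": 4, "AAA": 5, "AAG": 5,
                  "ATT": 3, "ATC": 2, "CTT": 4, "CTA": 4}
        doubled = {c: 2 * n for c, n in counts.items()}
        assert C.enc(doubled) == pytest.approx(wright_enc(doubled), abs=1e-9)
        assert C.enc(doubled) != pytest.approx(C.enc(counts), abs=1e-6)


class TestCai:
    def test_all_best_codons_gives_one(self):
        w = {c: 1.0 for c in SENSE}
        assert C.cai({"GCT": 30, "AAA": 10}, w) == pytest.approx(1.0)

    def test_constant_half_weight(self):
        w = {c: 0.5 for c in SENSE}
        assert C.cai({"GCT": 5, "AAA": 5}, w) == pytest.approx(0.5)

    def test_geometric_mean_mixture(self):
        w = {"GCT": 1.0, "AAA": 0.25}
        assert C.cai({"GCT": 10, "AAA": 10}, w) == pytest.approx(0.5)

    def test_single_codon_amino_acids_excluded(self):
        w = {"GCT": 0.8, "ATG": 1.0, "TGG": 1.0}
        assert C.cai({"GCT": 4, "ATG": 9, "TGG": 9}, w) == pytest.approx(0.8)

    def test_zero_weight_instructs_smoothing(self):
        with pytest.raises(ValueError, match="smoothing"):
            C.cai({"GCT": 1}, {"GCT": 0.0})

    def test_weights_from_reference_with_smoothing(self):
        w = C.cai_weights({"GCT": 9})
        assert w["GCT"] == 1.0
        assert 0 < w["GCC"] < 1  # absent codon smoothed, never zero


class TestCbiFop:
    def test_all_optimal(self):
        counts = {"GCT": 8}
        assert C.fop(counts, {"GCT"}) == 1.0
        assert C.cbi(counts, {"GCT"}) == pytest.approx(1.0)

    def test_hand_computed_fourfold_example(self):
        counts = {"GCT": 6, "GCC": 2}
        assert C.fop(counts, {"GCT"}) == pytest.approx(0.75)
        assert C.cbi(counts, {"GCT"}) == pytest.approx((6 - 2) / (8 - 2))

    def test_uniform_usage_cbi_near_zero(self):
        counts = {c: 100 for c in AA_TO_CODONS["A"]}
        assert abs(C.cbi(counts, {"GCT"})) < 0.01

    def test_degenerate_denominator_missing(self):
        # every codon of every family optimal -> N_ran == N_tot
        counts = {"GCT": 3, "GCC": 3}
        assert math.isnan(C.cbi(counts, set(AA_TO_CODONS["A"])))


class TestThirdPosition:
    def test_pure_c_ending(self):
        out = C.third_position_composition({"GCC": 10})
        assert out["c3s"] == 1.0 and out["gc3s"] == 1.0

    def test_pure_a_ending(self):
        out = C.third_position_composition({"GCA": 10})
        assert out["a3s"] == 1.0 and out["gc3s"] == 0.0

    def test_only_nondegenerate_codons_missing_shares(self):
        out = C.third_position_composition({"ATG": 1, "TGG": 1})
        assert math.isnan(out["a3s"]) and not math.isnan(out["gc"])

    @settings(derandomize=True, max_examples=40)
    @given(random_counts)
    def test_shares_sum_to_one(self, counts):
        out = C.third_position_composition(counts)
        if not math.isnan(out["a3s"]):
            assert out["a3s"] + out["t3s"] + out["g3s"] + out["c3s"] == pytest.approx(
                1.0, abs=1e-9
            )


class TestOptimalCodons:
    def test_dominant_codon_included(self):
        p = C.profile_gene("g", "GCTGCTGCTGCC")
        assert "GCT" in C.optimal_codons([p])

    def test_uniform_usage_gives_empty_set(self):
        cds = "".join(AA_TO_CODONS["A"]) + "".join(AA_TO_CODONS["G"])
        assert C.optimal_codons([C.profile_gene("g", cds)]) == set()

    def test_recovers_designated_codons_from_biased_family(self):
        from pcfam.synthetic import DESIGNATED_CODONS, _reverse_translate, _rng

        rng = _rng(5, "bias-test")
        protein = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 4000))
        profiles = [
            C.profile_gene(f"g{i}", _reverse_translate(protein, rng, 0.8))
            for i in range(5)
        ]
        expected = {
            DESIGNATED_CODONS[aa]
            for aa, cs in AA_TO_CODONS.items()
            if len(cs) > 1
        }
        assert C.optimal_codons(profiles) == expected


def gc3_gradient_profiles(n_genes=24, length=600, seed=0):
    """Synthetic gradient of joint G/C third-position bias."""
    rng = np.random.default_rng(seed)
    degenerate = [aa for aa, cs in AA_TO_CODONS.items() if len(cs) > 1]
    profiles = []
    ref_counts = None
    for i in range(n_genes):
        t = 0.05 + 0.9 * i / (n_genes - 1)
        codons = []
        for _ in range(length):
            aa = degenerate[rng.integers(len(degenerate))]
            gc_enders = [c for c in AA_TO_CODONS[aa] if c[2] in "GC"]
            at_enders = [c for c in AA_TO_CODONS[aa] if c[2] in "AT"]
            pool = gc_enders if (gc_enders and rng.random() < t) else (at_enders or gc_enders)
            codons.append(pool[rng.integers(len(pool))])
        cds = "".join(codons)
        if i == n_genes - 1:
            ref_counts = C.count_codons(cds)
        profiles.append(cds)
    weights = C.cai_weights(ref_counts)
    optimal = {c for c, v in C.rscu(ref_counts).items() if v > 1.0}
    return [
        C.profile_gene(f"g{i}", cds, weights, optimal) for i, cds in enumerate(profiles)
    ]


class TestCorrelations:
    def test_diagonal_is_one(self, small_family):
        profiles = [C.profile_gene(g.gene_id, g.cds) for g in small_family.genes]
        corr = C.index_correlations(profiles)
        for c in ("gc", "gc3s", "enc"):
            assert corr.loc[c, c] == pytest.approx(1.0)

    def test_directionality_on_gc3_gradient(self):
        corr = C.index_correlations(gc3_gradient_profiles())
        assert corr.loc["gc3s", "g3s"] > 0
        assert corr.loc["gc3s", "c3s"] > 0
        assert corr.loc["gc3s", "a3s"] < 0
        assert corr.loc["gc3s", "t3s"] < 0
        assert corr.loc["fop", "cai"] > 0
        assert corr.loc["fop", "cbi"] > 0

    def test_needs_three_profiles(self):
        p = C.profile_gene("g", "GCTGCC")
        with pytest.raises(ValueError):
            C.index_correlations([p, p])
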