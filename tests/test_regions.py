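"""Annotation, enrichment testing, CAGE region building, gene-set nulls, NS/S."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from clonesoma import regions as rg
from clonesoma.discovery import SomaticCatalog
from clonesoma.regions import (FantomThresholds, GeneModel, RegionSet,
                               annotate_catalog, build_fantom_regions,
                               disease_gene_null, enrichment_depletion,
                               gene_set_load, ns_s_ratio, regional_mutation_load)


def make_catalog(rows, clone="c1"):
    df = pd.DataFrame(rows)
    if "clone" not in df:
        df["clone"] = clone
    if "var_class" not in df:
        df["var_class"] = "SNV"
    df["accepted"] = True
    df["reason"] = ""
    return SomaticCatalog(df)


@pytest.fixture
def toy_gene_model():
    # one coding gene on +, exons [1000,1300) and [2000,2300); span [1000,2300)
    genes = pd.DataFrame([
        {"chrom": "chr1", "start": 1000, "end": 2300, "strand": "+",
         "gene": "GENE1", "coding": True},
    ])
    features = pd.DataFrame([
        {"chrom": "chr1", "start": 1000, "end": 1300, "strand": "+",
         "gene": "GENE1", "feature": "exon"},
        {"chrom": "chr1", "start": 2000, "end": 2300, "strand": "+",
         "gene": "GENE1", "feature": "exon"},
        {"chrom": "chr1", "start": 880, "end": 1000, "strand": "+",
         "gene": "GENE1", "feature": "five_utr"},
        {"chrom": "chr1", "start": 2300, "end": 2450, "strand": "+",
         "gene": "GENE1", "feature": "three_utr"},
    ])
    return GeneModel(genes=genes, features=features)


class TestAnnotate:
    def test_exon_hit(self, toy_gene_model):
        cat = annotate_catalog(make_catalog(
            [{"chrom": "chr1", "pos": 1101, "ref": "A", "alt": "T"}]), toy_gene_model)
        assert cat.records["annotation"].tolist() == ["exon"]
        assert cat.records["gene"].tolist() == ["GENE1"]

    def test_upstream_gene_within_5kb(self):
        # 3 kb 5' of a plus-strand gene with no other feature there
        genes = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 12_000,
                               "strand": "+", "gene": "G9", "coding": True}])
        features = pd.DataFrame([{"chrom": "chr1", "start": 10_000, "end": 12_000,
                                  "strand": "+", "gene": "G9", "feature": "exon"}])
        gm = GeneModel(genes, features)
        cat = annotate_catalog(make_catalog(
            [{"chrom": "chr1", "pos": 7001, "ref": "A", "alt": "T"}]), gm)
        assert cat.records["annotation"].tolist() == ["upstream_gene"]

    def test_intron_vs_splice_region(self, toy_gene_model):
        # deep intron at 1650 (0-based 1649); splice region within 8 bp of exon end
        cat = annotate_catalog(make_catalog([
            {"chrom": "chr1", "pos": 1650, "ref": "A", "alt": "T"},
            {"chrom": "chr1", "pos": 1303, "ref": "A", "alt": "T"},
        ]), toy_gene_model)
        assert cat.records["annotation"].tolist() == ["intron", "splice_region"]

    def test_intergenic_far_away(self, toy_gene_model):
        cat = annotate_catalog(make_catalog(
            [{"chrom": "chr1", "pos": 50_000, "ref": "A", "alt": "T"}]), toy_gene_model)
        assert cat.records["annotation"].tolist() == ["intergenic"]

    def test_class_percentages_partition(self, toy_gene_model):
        rows = [{"chrom": "chr1", "pos": p, "ref": "A", "alt": "T"}
                for p in (1101, 1650, 950, 2350, 9000, 50_000)]
        cat = annotate_catalog(make_catalog(rows), toy_gene_model)
        pct = rg.annotation_percentages(cat)
        assert pct.sum(axis=1).to_numpy() == pytest.approx([100.0])


class TestEnrichment:
    def test_whole_genome_region_is_neutral(self):
        region = RegionSet("all", pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 10_000}]))
        cat = pd.DataFrame({"chrom": ["chr1"] * 50,
                            "pos": np.linspace(1, 9999, 50, dtype=int)})
        res = enrichment_depletion(cat, region, callable_length=10_000)
        assert res.observed == 50
        assert res.expected == pytest.approx(50)
        assert res.log2_ratio == pytest.approx(0.0)

    def test_worked_binomial_example(self):
        """100 mutations, region 8% of genome, 2 observed -> P(X<=2) = 0.01127."""
        region = RegionSet("r", pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 8_000}]))
        pos = np.concatenate([np.linspace(1, 7999, 2, dtype=int),
                              np.linspace(8001, 99_999, 98, dtype=int)])
        cat = pd.DataFrame({"chrom": ["chr1"] * 100, "pos": pos})
        res = enrichment_depletion(cat, region, callable_length=100_000)
        assert res.observed == 2
        assert res.expected == pytest.approx(8.0)
        assert res.p == pytest.approx(float(binom.cdf(2, 100, 0.08)), rel=1e-9)
        assert res.p == pytest.approx(0.01127, abs=5e-5)

    def test_zero_observed_gives_sentinel(self):
        region = RegionSet("r", pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 5_000}]))
        cat = pd.DataFrame({"chrom": ["chr1"] * 10, "pos": [6000 + i for i in range(10)]})
        res = enrichment_depletion(cat, region, callable_length=100_000)
        assert res.observed == 0
        assert res.log2_ratio == float("-inf")
        assert res.direction == "depletion"

    def test_zero_callable_length_rejected(self):
        region = RegionSet("r", pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 100}]))
        with pytest.raises(ValueError):
            enrichment_depletion(pd.DataFrame({"chrom": [], "pos": []}), region, 0)

    def test_pvalues_uniform_under_uniform_placement(self):
        """Fixed-direction depletion p-values are uniform over simulated catalogs."""
        from scipy.stats import kstest
        region = RegionSet("r", pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 100_000}]))
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            pos = rng.integers(1, 1_000_000, size=2000)
            cat = pd.DataFrame({"chrom": ["chr1"] * 2000, "pos": pos})
            res = enrichment_depletion(cat, region, 1_000_000, direction="depletion")
            pvals.append(res.p)
        assert kstest(pvals, "uniform").pvalue > 0.01


def expr_table(rows):
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end",
                                       "strand", "kind", "gene",
                                       "rep1", "rep2", "rep3"])


class TestFantom:
    def test_enhancer_padding(self, toy_gene_model):
        day0 = expr_table([("e1", "chr1", 1000, 1200, ".", "enhancer", "", 1.0, 0, 0)])
        day1 = expr_table([("e1", "chr1", 1000, 1200, ".", "enhancer", "", 1.0, 0, 0)])
        out = build_fantom_regions({"day00": day0, "day01": day1},
                                   FantomThresholds(), toy_gene_model)
        iv = out[("basal", "enhancers")].intervals
        assert iv[["start", "end"]].to_numpy().tolist() == [[900, 1300]]

    def test_promoter_below_threshold_excluded(self, toy_gene_model):
        day0 = expr_table([("p1", "chr1", 5000, 5100, "+", "promoter", "GENE1", 29, 29, 29)])
        out = build_fantom_regions({"day00": day0, "day01": day0},
                                   FantomThresholds(), toy_gene_model)
        assert len(out[("basal", "promoters")].intervals) == 0

    def test_plus_strand_promoter_window(self, toy_gene_model):
        day0 = expr_table([("p1", "chr1", 5000, 5100, "+", "promoter", "GENE1", 35, 0, 0)])
        out = build_fantom_regions({"day00": day0, "day01": day0},
                                   FantomThresholds(), toy_gene_model)
        iv = out[("basal", "promoters")].intervals
        assert iv[["start", "end"]].to_numpy().tolist() == [[4140, 5200]]

    def test_minus_strand_promoter_window(self, toy_gene_model):
        day0 = expr_table([("p1", "chr1", 5000, 5100, "-", "promoter", "GENE1", 35, 0, 0)])
        out = build_fantom_regions({"day00": day0, "day01": day0},
                                   FantomThresholds(), toy_gene_model)
        iv = out[("basal", "promoters")].intervals
        assert iv[["start", "end"]].to_numpy().tolist() == [[4900, 5960]]

    def test_missing_strand_is_an_error(self, toy_gene_model):
        day0 = expr_table([("p1", "chr1", 5000, 5100, ".", "promoter", "GENE1", 35, 0, 0)])
        with pytest.raises(ValueError, match="strand"):
            build_fantom_regions({"day00": day0, "day01": day0},
                                 FantomThresholds(), toy_gene_model)

    def test_day0_region_is_basal_only(self, toy_gene_model):
        row = ("p1", "chr1", 5000, 5100, "+", "promoter", "GENE1", 35, 0, 0)
        out = build_fantom_regions({"day00": expr_table([row]),
                                    "day06": expr_table([row])},
                                   FantomThresholds(), toy_gene_model)
        assert len(out[("basal", "promoters")].intervals) == 1
        assert len(out[("upon_differentiation", "promoters")].intervals) == 0

    def test_basal_and_upon_differentiation_disjoint(self, sim_config, reference):
        from clonesoma import simulate
        tables = simulate.simulate_expression_table(sim_config, reference)
        out = build_fantom_regions(tables, FantomThresholds(), reference.gene_model)
        for kind in ("promoters", "enhancers"):
            basal = out[("basal", kind)].intervals
            upon = out[("upon_differentiation", kind)].intervals
            inter = rg.intersect_intervals(basal, upon)
            assert len(inter) == 0 or (inter["end"] - inter["start"]).sum() == 0

    def test_all_zero_scores_give_empty_sets(self, toy_gene_model):
        day0 = expr_table([("p1", "chr1", 5000, 5100, "+", "promoter", "GENE1", 0, 0, 0),
                           ("e1", "chr1", 9000, 9100, ".", "enhancer", "", 0, 0, 0)])
        out = build_fantom_regions({"day00": day0, "day01": day0},
                                   FantomThresholds(), toy_gene_model)
        for rs in out.values():
            assert len(rs.intervals) == 0

    def test_exons_follow_expressed_promoters(self, toy_gene_model):
        day0 = expr_table([("p1", "chr1", 880, 930, "+", "promoter", "GENE1", 35, 0, 0)])
        out = build_fantom_regions({"day00": day0, "day01": day0},
                                   FantomThresholds(), toy_gene_model)
        assert len(out[("basal", "exons")].intervals) == 2


class TestLoad:
    def region_sets(self):
        return {"setA": RegionSet("setA", pd.DataFrame(
            [{"chrom": "chr1", "start": 0, "end": 1000}]))}

    def test_fold_change_arithmetic(self):
        rows = []
        for i in range(10):
            rows.append({"clone": "young1", "chrom": "chr1", "pos": 10 + i,
                         "ref": "A", "alt": "T"})
        for i in range(24):
            rows.append({"clone": "old1", "chrom": "chr1", "pos": 10 + i,
                         "ref": "A", "alt": "T"})
        cat = make_catalog(rows)
        res = regional_mutation_load(cat, self.region_sets(),
                                     {"young1": "young", "old1": "old"})
        assert res["fold_old_vs_young"]["setA"] == pytest.approx(2.4)

    def test_counts_invariant_to_clone_order(self):
        rows = [{"clone": c, "chrom": "chr1", "pos": p, "ref": "A", "alt": "T"}
                for c, p in [("a", 5), ("b", 10), ("b", 2000)]]
        cat1 = make_catalog(rows)
        cat2 = make_catalog(rows[::-1])
        groups = {"a": "young", "b": "old"}
        r1 = regional_mutation_load(cat1, self.region_sets(), groups)
        r2 = regional_mutation_load(cat2, self.region_sets(), groups)
        pd.testing.assert_frame_equal(r1["counts"], r2["counts"])

    def test_no_mutations_all_zero(self):
        cat = make_catalog([{"clone": "a", "chrom": "chr2", "pos": 5,
                             "ref": "A", "alt": "T"}])
        res = regional_mutation_load(cat, self.region_sets(),
                                     {"a": "young", "b": "old"})
        assert (res["counts"]["setA"] == 0).all()


class TestGeneSet:
    def test_average_arithmetic(self):
        cat = pd.DataFrame({"gene": ["G1"] * 13})
        res = gene_set_load(cat, [f"G{i}" for i in range(1, 101)],
                            n_clones=13, n_genes=100)
        assert res["n_mutations"] == 13
        assert res["average_per_gene"] == pytest.approx(0.01)

    def test_case_normalization(self):
        cat = pd.DataFrame({"gene": ["ttn", "TTN"]})
        res = gene_set_load(cat, ["Ttn"], n_clones=1)
        assert res["n_mutations"] == 2

    def test_zero_hits(self):
        cat = pd.DataFrame({"gene": ["OTHER"]})
        assert gene_set_load(cat, ["G1"], n_clones=2)["average_per_gene"] == 0

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            gene_set_load(pd.DataFrame({"gene": []}), [], n_clones=1)


class TestDiseaseNull:
    exons = pd.DataFrame({
        "gene": ["G1", "G2", "G3", "G4"],
        "start": [0, 0, 0, 0],
        "end": [100, 200, 300, 400],
    })

    def test_saturated_set_gives_p_one(self):
        res = disease_gene_null(20, self.exons, ["G1", "G2", "G3", "G4"],
                                observed_in_set=20, n_resamples=500, seed=0)
        assert res.p == 1.0

    def test_seed_reproducible(self):
        r1 = disease_gene_null(10, self.exons, ["G3"], 5, n_resamples=200, seed=3)
        r2 = disease_gene_null(10, self.exons, ["G3"], 5, n_resamples=200, seed=3)
        np.testing.assert_array_equal(r1.null_counts, r2.null_counts)

    def test_null_drawn_set_has_zero_z(self):
        """When the observed count equals the null mean, |Z| is near zero."""
        # disease set G3+G4: p = 700/1000; with 100 draws the null mean is 70
        res = disease_gene_null(100, self.exons, ["G3", "G4"],
                                observed_in_set=70, n_resamples=100_000, seed=1)
        assert abs(res.z_score) < 0.1

    def test_zero_length_exons_excluded(self):
        exons = pd.DataFrame({"gene": ["G1", "G2"], "start": [0, 50], "end": [100, 50]})
        res = disease_gene_null(5, exons, ["G2"], 0, n_resamples=100, seed=0)
        assert res.null_mean == 0  # G2's zero-length exon can never be drawn


class TestNsS:
    @pytest.fixture
    def coding_setup(self):
        # chr1: gene of one exon [10, 19), CDS = TTT TAC GGA (+ strand)
        seq = "A" * 10 + "TTTTACGGA" + "A" * 10
        genes = pd.DataFrame([{"chrom": "chr1", "start": 10, "end": 19,
                               "strand": "+", "gene": "G1", "coding": True}])
        features = pd.DataFrame([{"chrom": "chr1", "start": 10, "end": 19,
                                  "strand": "+", "gene": "G1", "feature": "exon"}])
        return GeneModel(genes, features), {"chr1": seq}

    def test_third_position_synonymous(self, coding_setup):
        gm, ref = coding_setup
        # TTT -> TTC (Phe->Phe): position 0-based 12, 1-based 13
        cat = make_catalog([{"chrom": "chr1", "pos": 13, "ref": "T", "alt": "C"}])
        res = ns_s_ratio(cat, gm, ref)
        assert res["counts"]["c1"] == {"non_synonymous": 0, "synonymous": 1}

    def test_stop_gain_is_non_synonymous(self, coding_setup):
        gm, ref = coding_setup
        # TAC -> TAA at codon 2 third position (0-based 15 -> 1-based 16)
        cat = make_catalog([{"chrom": "chr1", "pos": 16, "ref": "C", "alt": "A"}])
        res = ns_s_ratio(cat, gm, ref)
        assert res["counts"]["c1"] == {"non_synonymous": 1, "synonymous": 0}

    def test_ratio_arithmetic(self, coding_setup):
        gm, ref = coding_setup
        rows = [
            # 4 non-synonymous: TTT->ATT etc. (first positions)
            {"chrom": "chr1", "pos": 11, "ref": "T", "alt": "A"},
            {"chrom": "chr1", "pos": 12, "ref": "T", "alt": "A"},
            {"chrom": "chr1", "pos": 14, "ref": "T", "alt": "A"},
            {"chrom": "chr1", "pos": 15, "ref": "A", "alt": "T"},
            # 2 synonymous: TTT->TTC, GGA->GGG
            {"chrom": "chr1", "pos": 13, "ref": "T", "alt": "C"},
            {"chrom": "chr1", "pos": 19, "ref": "A", "alt": "G"},
        ]
        res = ns_s_ratio(make_catalog(rows), gm, ref)
        assert res["ratios"]["c1"] == pytest.approx(2.0)

    def test_minus_strand_codon(self):
        # same CDS read on minus strand: genome is revcomp of TTTTACGGA
        cds = "TTTTACGGA"
        comp = str.maketrans("ACGT", "TGCA")
        seq = "A" * 10 + cds.translate(comp)[::-1] + "A" * 10
        genes = pd.DataFrame([{"chrom": "chr1", "start": 10, "end": 19,
                               "strand": "-", "gene": "G1", "coding": True}])
        features = pd.DataFrame([{"chrom": "chr1", "start": 10, "end": 19,
                                  "strand": "-", "gene": "G1", "feature": "exon"}])
        gm = GeneModel(genes, features)
        # third codon base of codon 1 (TTT): genome 0-based 16 (= cds index 2),
        # genome base is A (complement of T); T->C on cds = A->G on genome
        cat = make_catalog([{"chrom": "chr1", "pos": 17, "ref": "A", "alt": "G"}])
        res = ns_s_ratio(cat, gm, {"chr1": seq})
        assert res["counts"]["c1"] == {"non_synonymous": 0, "synonymous": 1}

    def test_group_comparison_runs(self, coding_setup):
        gm, ref = coding_setup
        rows = []
        for clone, grp_pos in [("y1", 13), ("o1", 11)]:
            rows.append({"clone": clone, "chrom": "chr1", "pos": grp_pos,
                         "ref": ref["chr1"][grp_pos - 1], "alt": "C"})
            rows.append({"clone": clone, "chrom": "chr1", "pos": 19,
                         "ref": "A", "alt": "G"})
        res = ns_s_ratio(make_catalog(rows), gm, ref,
                         groups={"y1": "young", "o1": "old"})
        assert "p_value" in res
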