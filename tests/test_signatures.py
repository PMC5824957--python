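"""Spectrum construction, NMF extraction, refitting, trends, clustering."""

import numpy as np
import pandas as pd
import pytest

from clonesoma import signatures
from clonesoma.discovery import SomaticCatalog
from clonesoma.signatures import (SPECTRUM_INDEX, Spectrum96, build_spectrum,
                                  cluster_clones, extract_signatures,
                                  load_reference_signatures, match_profiles,
                                  nmf_objective_trace, refit_to_reference)


def catalog_from(rows):
    df = pd.DataFrame(rows)
    df["accepted"] = True
    df["reason"] = ""
    df["var_class"] = ["SNV" if len(r) == 1 and len(a) == 1 else "indel"
                       for r, a in zip(df["ref"], df["alt"])]
    if "clone" not in df:
        df["clone"] = "c1"
    return SomaticCatalog(df)


class TestSpectrum:
    def test_single_snv_in_canonical_class(self):
        # A C G around position 2 (1-based), C>T
        cat = catalog_from([{"clone": "c1", "chrom": "chr1", "pos": 2, "ref": "C", "alt": "T"}])
        sp = build_spectrum(cat, {"chr1": "ACGA"})
        assert sp.total == 1
        assert sp.as_series()["A[C>T]G"] == 1

    def test_purine_reference_collapses_by_revcomp(self):
        # C G T with G>A at center: revcomp -> A[C>T]G
        cat = catalog_from([{"clone": "c1", "chrom": "chr1", "pos": 2, "ref": "G", "alt": "A"}])
        sp = build_spectrum(cat, {"chr1": "CGTA"})
        assert sp.as_series()["A[C>T]G"] == 1

    def test_spectrum_conserves_snv_count(self, cohort, reference):
        clones, _, _ = cohort
        from clonesoma.discovery import FilterParams, filter_somatic
        cat = filter_somatic([o for o in clones[0].observations], FilterParams())
        sp = build_spectrum(cat, reference.sequences, clone=clones[0].clone)
        n_snv = (cat.accepted[cat.accepted["clone"] == clones[0].clone]["var_class"] == "SNV").sum()
        assert sp.total + sp.n_unresolvable == n_snv

    def test_contig_edge_positions_excluded(self):
        cat = catalog_from([{"clone": "c1", "chrom": "chr1", "pos": 1, "ref": "A", "alt": "T"}])
        sp = build_spectrum(cat, {"chr1": "ACGA"})
        assert sp.total == 0 and sp.n_unresolvable == 1

    def test_strand_collapse_idempotent(self):
        """Reverse-complementing reference and variants leaves the spectrum unchanged."""
        seq = "ACGTTGCAACGTCGATCGGA"
        rows = [{"clone": "c1", "chrom": "chr1", "pos": 4, "ref": "T", "alt": "A"},
                {"clone": "c1", "chrom": "chr1", "pos": 12, "ref": "T", "alt": "C"},
                {"clone": "c1", "chrom": "chr1", "pos": 7, "ref": "G", "alt": "T"}]
        sp_fwd = build_spectrum(catalog_from(rows), {"chr1": seq})
        comp = str.maketrans("ACGT", "TGCA")
        rc_seq = seq.translate(comp)[::-1]
        rc_rows = [{"clone": "c1", "chrom": "chr1", "pos": len(seq) - r["pos"] + 1,
                    "ref": r["ref"].translate(comp), "alt": r["alt"].translate(comp)}
                   for r in rows]
        sp_rev = build_spectrum(catalog_from(rc_rows), {"chr1": rc_seq})
        np.testing.assert_array_equal(sp_fwd.counts, sp_rev.counts)


class TestNmf:
    def test_rank1_identical_spectra_recovers_common_profile(self):
        rng = np.random.default_rng(0)
        common = rng.dirichlet(np.ones(96))
        V = pd.DataFrame(np.outer(common, [100, 200, 300]),
                         index=list(SPECTRUM_INDEX), columns=["a", "b", "c"])
        sig = extract_signatures(V, rank=1, n_restarts=3, seed=0)
        prof = sig.profiles.iloc[:, 0].to_numpy()
        cos = prof @ common / (np.linalg.norm(prof) * np.linalg.norm(common))
        assert cos > 0.9999
        np.testing.assert_allclose(sig.contributions.to_numpy().ravel(),
                                   [100, 200, 300], rtol=1e-3)

    def test_objective_non_increasing(self):
        rng = np.random.default_rng(1)
        V = rng.poisson(5.0, size=(96, 8)).astype(float)
        trace = nmf_objective_trace(V, rank=3, seed=2, max_iter=50)
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_all_zero_matrix_rejected(self):
        V = pd.DataFrame(np.zeros((96, 5)), index=list(SPECTRUM_INDEX))
        with pytest.raises(ValueError, match="zero"):
            extract_signatures(V, rank=2)

    def test_objective_invariant_to_column_permutation(self):
        rng = np.random.default_rng(3)
        V = pd.DataFrame(rng.poisson(8.0, size=(96, 10)).astype(float),
                         index=list(SPECTRUM_INDEX),
                         columns=[f"c{i}" for i in range(10)])
        s1 = extract_signatures(V, rank=2, n_restarts=5, seed=9)
        s2 = extract_signatures(V[list(V.columns[::-1])], rank=2, n_restarts=5, seed=9)
        assert s1.objective == pytest.approx(s2.objective, rel=1e-4)


class TestRefit:
    def test_exact_member_recovered(self):
        panel = load_reference_signatures()
        spectrum = 100 * panel["RS1"].to_numpy()
        coef = refit_to_reference(spectrum, panel)
        assert coef["RS1"] == pytest.approx(100, rel=1e-6)
        assert coef.drop("RS1").abs().max() < 1e-6

    def test_constructed_mixture_recovered(self):
        panel = load_reference_signatures()
        spectrum = 60 * panel["RS5"].to_numpy() + 40 * panel["RS8"].to_numpy()
        coef = refit_to_reference(spectrum, panel)
        assert coef["RS5"] == pytest.approx(60, abs=1e-6)
        assert coef["RS8"] == pytest.approx(40, abs=1e-6)

    def test_zero_spectrum_gives_zero_vector(self):
        panel = load_reference_signatures()
        coef = refit_to_reference(np.zeros(96), panel)
        assert (coef == 0).all()

    def test_in_cone_reconstruction_is_exact(self):
        panel = load_reference_signatures()
        mix = panel.to_numpy() @ np.linspace(10, 40, panel.shape[1])
        coef = refit_to_reference(mix, panel)
        resid = np.linalg.norm(mix - panel.to_numpy() @ coef.to_numpy())
        assert resid < 1e-6

    def test_dimension_mismatch(self):
        panel = load_reference_signatures()
        with pytest.raises(ValueError):
            refit_to_reference(np.zeros(50), panel)


class TestAgeTrend:
    def test_exact_linear_contributions_recovered(self):
        ages = np.array([20.0, 30, 40, 55, 70, 80])
        meta = pd.DataFrame({"clone": [f"c{i}" for i in range(6)],
                             "donor": [f"d{i}" for i in range(6)],
                             "age": ages})
        contrib = pd.DataFrame(
            [100 + 7.0 * ages, 50 + 3.0 * ages, 10 + 2.0 * ages],
            index=["s1", "s2", "s3"], columns=meta["clone"])
        fits = signatures.signature_age_trend(contrib, meta, n_tested=3)
        assert [f.slope for f in fits] == pytest.approx([7.0, 3.0, 2.0], abs=1e-5)
        for f in fits:
            assert f.p_adjusted == min(1.0, 3 * f.p_raw)


class TestCluster:
    def make_contrib(self, rng, shift=0.0):
        group1 = rng.dirichlet([20, 2, 2], size=8)
        group2 = rng.dirichlet([2, 20, 2], size=6) + shift
        X = np.vstack([group1, group2]) * 500
        clones = [f"c{i:02d}" for i in range(14)]
        return pd.DataFrame(X.T, index=["s1", "s2", "s3"], columns=clones)

    def test_two_separated_groups_recovered(self):
        contrib = self.make_contrib(np.random.default_rng(0))
        res = cluster_clones(contrib, n_perm=50, seed=1)
        labels = res["labels"]
        assert set(labels[:8]) == {0} and set(labels[8:]) == {1}

    def test_labels_invariant_to_input_order(self):
        contrib = self.make_contrib(np.random.default_rng(0))
        res1 = cluster_clones(contrib, n_perm=50, seed=1)
        shuffled = contrib[list(contrib.columns[::-1])]
        res2 = cluster_clones(shuffled, n_perm=50, seed=1)
        assert res1["labels"].sort_index().equals(res2["labels"].sort_index())

    def test_identical_clones_flagged_degenerate(self):
        contrib = pd.DataFrame(np.tile([[10.0], [5.0], [1.0]], 6),
                               index=["s1", "s2", "s3"],
                               columns=[f"c{i}" for i in range(6)])
        res = cluster_clones(contrib, n_perm=10, seed=0)
        assert res["degenerate"]

    def test_k_larger_than_clones_rejected(self):
        contrib = pd.DataFrame(np.ones((3, 2)), index=["s1", "s2", "s3"],
                               columns=["a", "b"])
        with pytest.raises(ValueError):
            cluster_clones(contrib, k=5)
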