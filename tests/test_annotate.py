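"""Biotype scores, enrichment tests, category cascade, epistates, eQTLs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from polatlas.annotate import (BiotypeScores, bh_fdr, binomial_overlap_test,
                               biotype_scores, classify_consensus,
                               epistate_proportions, eqtl_enrichment,
                               hypergeom_subset_test)
from polatlas.genomic_io import IntervalSet


def occupancy(matrix, datasets, biotypes):
    M = pd.DataFrame(np.asarray(matrix, dtype=bool), index=datasets)
    ds = pd.DataFrame({"dataset_id": datasets, "biotype": biotypes})
    return M, ds


class TestBiotypeScores:
    def test_single_biotype_consensus_has_zero_diversity(self):
        M, ds = occupancy([[1], [1], [0]], ["a", "b", "c"],
                          ["blood", "blood", "brain"])
        scores = biotype_scores(M, ds)
        assert scores.lam.iloc[0] == 0.0
        assert scores.dominant.iloc[0] == "blood"

    def test_equidistributed_sixteen_biotypes(self):
        # 16 biotypes, one dataset each, all bound at one consensus
        datasets = [f"d{i}" for i in range(16)]
        M, ds = occupancy(np.ones((16, 1)), datasets,
                          [f"b{i}" for i in range(16)])
        scores = biotype_scores(M, ds)
        assert scores.lam.iloc[0] == pytest.approx(1 - 16 * (1 / 16) ** 2)

    def test_normalization_prevents_peak_rich_biotype_dominance(self):
        # biotype A: 10 total events, 1 here; biotype B: 100 total, 1 here
        cols = 1 + 9 + 99  # consensus 0 shared; 9 A-only; 99 B-only
        Ma = np.zeros((2, cols), dtype=bool)
        Ma[0, 0] = Ma[1, 0] = True
        Ma[0, 1:10] = True
        Ma[1, 10:] = True
        M, ds = occupancy(Ma, ["dsA", "dsB"], ["A", "B"])
        scores = biotype_scores(M, ds)
        assert scores.n.loc["A", 0] == pytest.approx(0.1)
        assert scores.n.loc["B", 0] == pytest.approx(0.01)
        assert scores.dominant[0] == "A"

    def test_all_zero_column_flagged_missing(self):
        M, ds = occupancy([[1, 0], [1, 0]], ["a", "b"], ["x", "y"])
        scores = biotype_scores(M, ds)
        assert np.isnan(scores.lam.iloc[1])
        assert scores.dominant.iloc[1] is np.nan

    def test_invariant_to_dataset_order_and_duplication(self):
        rng = np.random.default_rng(0)
        Ma = rng.random((6, 30)) < 0.4
        datasets = [f"d{i}" for i in range(6)]
        biotypes = ["x", "x", "y", "y", "z", "z"]
        M, ds = occupancy(Ma, datasets, biotypes)
        base = biotype_scores(M, ds)

        perm = rng.permutation(6)
        Mp = M.iloc[perm]
        dsp = ds.iloc[perm].reset_index(drop=True)
        permuted = biotype_scores(Mp, dsp)
        pd.testing.assert_frame_equal(base.n, permuted.n)

        # duplicating every dataset of one biotype leaves n unchanged
        Md = pd.concat([M, M.loc[["d0", "d1"]].rename(index={"d0": "d0b", "d1": "d1b"})])
        dsd = pd.concat([ds, pd.DataFrame({"dataset_id": ["d0b", "d1b"],
                                           "biotype": ["x", "x"]})],
                        ignore_index=True)
        doubled = biotype_scores(Md, dsd)
        pd.testing.assert_frame_equal(base.n, doubled.n)

    def test_missing_biotype_label_rejected(self):
        M = pd.DataFrame([[True]], index=["a"])
        ds = pd.DataFrame({"dataset_id": ["other"], "biotype": ["x"]})
        with pytest.raises(KeyError):
            biotype_scores(M, ds)


class TestBinomialOverlap:
    def test_exact_tail_probability(self):
        row = binomial_overlap_test(k=4, n_trials=4, feature_coverage=50,
                                    universe_coverage=100)
        assert row["p_value"] == pytest.approx(1 / 16, rel=1e-12)
        assert row["fold_change"] == pytest.approx(2.0)

    def test_fold_one_at_expectation(self):
        row = binomial_overlap_test(k=10, n_trials=100, feature_coverage=10,
                                    universe_coverage=100)
        assert row["fold_change"] == pytest.approx(1.0)

    def test_zero_hits(self):
        row = binomial_overlap_test(k=0, n_trials=50, feature_coverage=10,
                                    universe_coverage=100)
        assert row["p_value"] == 1.0 and row["fold_change"] == 0.0

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            binomial_overlap_test(1, 1, 0, 0)


class TestHypergeomSubset:
    def test_exact_enumeration_value(self):
        row = hypergeom_subset_test(N=10, K=5, n=4, k=4)
        assert row["p_value"] == pytest.approx(comb(5, 4) / comb(10, 4),
                                               rel=1e-12)

    def test_fold_one_at_integer_expectation(self):
        row = hypergeom_subset_test(N=100, K=20, n=10, k=2)
        assert row["fold_change"] == pytest.approx(1.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_subset_test(N=10, K=5, n=4, k=5)

    def test_upper_tail_matches_full_enumeration(self):
        # enumerate all C(N, n) draws explicitly on a tiny instance
        from itertools import combinations
        N, K, n, k = 8, 3, 4, 2
        hits = 0
        total = 0
        for draw in combinations(range(N), n):
            total += 1
            hits += sum(1 for x in draw if x < K) >= k
        row = hypergeom_subset_test(N, K, n, k)
        assert row["p_value"] == pytest.approx(hits / total, rel=1e-9)

    def test_converges_to_binomial_at_large_population(self):
        n, k = 30, 9
        p = 0.2
        binom_p = binomial_overlap_test(k, n, p, 1.0)["p_value"]
        N = 200000
        hyper_p = hypergeom_subset_test(N, int(p * N), n, k)["p_value"]
        assert hyper_p == pytest.approx(binom_p, rel=5e-3)


class TestBhFdr:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_fdr(p)
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_ref)

    def test_empty(self):
        assert bh_fdr([]).size == 0


class TestClassifyConsensus:
    def make_consensus(self, centroids):
        return pd.DataFrame({"chrom": "chr1", "start": 0, "end": 1,
                             "centroid": centroids})

    def iv(self, *triples):
        return IntervalSet.from_dataframe(
            pd.DataFrame(triples, columns=["chrom", "start", "end"]))

    def test_promoter_beats_enhancer_in_cascade(self):
        refsets = {"Promoter-like": self.iv(("chr1", 90, 110)),
                   "Enhancer-like": self.iv(("chr1", 90, 110))}
        cats = classify_consensus(self.make_consensus([100]), refsets)
        assert cats.iloc[0] == "Promoter-like"

    def test_gene_tail_window_downstream_strand_aware(self):
        genes = pd.DataFrame([("chr1", 1000, 2000, "+"),
                              ("chr1", 50000, 60000, "-")],
                             columns=["chrom", "start", "end", "strand"])
        cats = classify_consensus(self.make_consensus([7000, 45000, 15000]),
                                  {}, genes=genes)
        # 7000 is 5 kb past gene1 end; 45000 is 5 kb upstream of gene2 start
        assert cats.tolist() == ["Gene-tail", "Gene-tail", "Unannotated"]

    def test_no_reference_hits_unannotated(self):
        cats = classify_consensus(self.make_consensus([5]), {})
        assert cats.iloc[0] == "Unannotated"


class TestEpistateProportions:
    def test_identical_subsets_yield_null_test(self):
        rng = np.random.default_rng(1)
        calls = pd.DataFrame(rng.choice(["TssA", "Enh", "Quies"], size=(40, 5)),
                             columns=[f"e{i}" for i in range(5)])
        # membership split irrelevant to state composition on average
        in_cluster = pd.Series([True] * 20 + [False] * 20)
        props, tests = epistate_proportions(in_cluster, calls)
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-9)

    def test_single_epigenome_returns_no_test(self):
        calls = pd.DataFrame({"e0": ["TssA", "Enh", "Enh", "Quies"]})
        props, tests = epistate_proportions(pd.Series([True, True, False, False]),
                                            calls)
        assert len(tests) == 0 and np.allclose(props.sum(axis=1), 1.0)

    def test_planted_state_enrichment_detected(self):
        rng = np.random.default_rng(2)
        n_regions, n_epi = 300, 10
        in_cluster = pd.Series(np.arange(n_regions) < 100)
        cols = {}
        for e in range(n_epi):
            states = rng.choice(["Enh", "Quies", "Tx"], size=n_regions,
                                p=[0.2, 0.5, 0.3])
            # enrich Enh 3x inside the cluster
            boost = rng.random(n_regions) < 0.4
            states = np.where(in_cluster & boost, "Enh", states)
            cols[f"e{e}"] = states
        props, tests = epistate_proportions(in_cluster, pd.DataFrame(cols))
        assert tests.loc["Enh", "p_value"] < 0.01
        assert tests.loc["Enh", "t"] > 0


class TestEqtlEnrichment:
    def build(self, seed=0, n_regions=300, planted=True):
        rng = np.random.default_rng(seed)
        tissues = ["liver", "heart", "brain"]
        regions = [f"r{i}" for i in range(n_regions)]
        markers = {}
        eqtl = {}
        for t_i, t in enumerate(tissues):
            m = np.zeros(n_regions, dtype=bool)
            m[t_i * 80:(t_i * 80) + 60] = True
            markers[t] = pd.Series(m, index=regions)
            e = rng.random(n_regions) < 0.03
            if planted:
                e |= m & (rng.random(n_regions) < 0.5)
            eqtl[t] = e
        return markers, pd.DataFrame(eqtl, index=regions)

    def test_matched_pairs_strongest_on_diagonal(self):
        markers, eqtl = self.build()
        p = eqtl_enrichment(markers, eqtl, tissue_frac_cap=0.4, min_markers=10)
        for t in p.index:
            off = [p.loc[t, u] for u in p.columns if u != t]
            assert p.loc[t, t] < min(off)

    def test_tissue_below_min_markers_dropped(self):
        markers, eqtl = self.build()
        idx = np.arange(len(markers["heart"]))
        markers["heart"] = pd.Series((idx >= 80) & (idx < 129),
                                     index=markers["heart"].index)
        p = eqtl_enrichment(markers, eqtl, tissue_frac_cap=0.4, min_markers=50)
        assert "heart" not in p.columns and "liver" in p.columns

    def test_no_eqtls_all_p_one(self):
        markers, eqtl = self.build(planted=False)
        eqtl[:] = False
        p = eqtl_enrichment(markers, eqtl, tissue_frac_cap=0.4, min_markers=10)
        assert (p.to_numpy() == 1.0).all()
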