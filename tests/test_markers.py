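"""Marker calling, differential regions, meta-clustering, pan-cancer calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from polatlas.markers import (differential_regions, expression_markers,
                              matching_vs_nonmatching, meta_cluster,
                              occupancy_markers, pancancer_threshold,
                              yule_distance_matrix)
from polatlas.simulate import SimConfig, simulate_count_matrix
from polatlas.transform import (detectability_rank, filter_low_counts,
                                fit_regularized_nb, pearson_residuals,
                                pooling_size_factors)


def run_transform(counts):
    counts = filter_low_counts(counts)
    _, top = detectability_rank(counts)
    sf = pooling_size_factors(counts.loc[top])
    model = fit_regularized_nb(counts, sf, seed=0)
    return counts, sf, pearson_residuals(counts, model)


class TestExpressionMarkers:
    def test_planted_upregulation_recovered_with_fdr_control(self):
        """2-fold effects at well-expressed regions (base mean >= 20, where a
        30-vs-30 Welch test has power) are recalled at >= 0.9 with FDR
        control."""
        recalls, fdrs = [], []
        for seed in range(3):
            cfg = SimConfig(seed=300 + seed, n_biotypes=2,
                            n_samples_per_biotype=30, effect_log2fc=1.0,
                            nb_mean_range=(20.0, 100.0), marker_fraction=0.1)
            counts, meta, truth = simulate_count_matrix(
                [f"r{i:04d}" for i in range(1000)], cfg)
            counts, sf, res = run_transform(counts)
            bt = meta.set_index("sample_id")["biotype"]
            mm = expression_markers(res, counts, bt, sf, source="sim")
            for b in ("blood", "brain"):
                called = set(mm.columns[mm.loc[("sim", b)]])
                planted = {r for r, x in truth.items()
                           if x == b and r in counts.index}
                if planted:
                    recalls.append(len(called & planted) / len(planted))
                    if called:
                        fdrs.append(len(called - planted) / len(called))
        assert np.mean(recalls) >= 0.9
        assert np.mean(fdrs if fdrs else [0]) <= 0.1

    def test_region_detected_in_single_group_sample_never_marker(self, expression):
        counts = expression["counts"].copy()
        res = expression["residuals"].copy()
        bt = expression["biotypes"]
        group = bt == bt.unique()[0]
        region = counts.index[0]
        counts.loc[region, :] = 0
        counts.loc[region, counts.columns[group.to_numpy()][0]] = 50
        res.loc[region, :] = 0.0
        res.loc[region, counts.columns[group.to_numpy()]] = 5.0
        mm = expression_markers(res, counts, bt, expression["size_factors"])
        assert not mm.loc[("rnaseq", bt.unique()[0]), region]

    def test_null_groups_yield_near_zero_markers(self):
        rates = []
        for seed in range(3):
            cfg = SimConfig(seed=400 + seed, n_biotypes=2,
                            n_samples_per_biotype=25, effect_log2fc=0.0)
            counts, meta, _ = simulate_count_matrix(
                [f"r{i:04d}" for i in range(400)], cfg)
            counts, sf, res = run_transform(counts)
            bt = meta.set_index("sample_id")["biotype"]
            mm = expression_markers(res, counts, bt, sf)
            rates.append(mm.to_numpy().mean())
        assert np.mean(rates) <= 0.075


class TestOccupancyMarkers:
    def test_biotype_exclusive_consensus_is_marker(self):
        # 5 datasets of biotype A among 50; consensus bound by exactly the 5
        n_ds = 50
        datasets = [f"d{i}" for i in range(n_ds)]
        biotype = pd.Series(["A"] * 5 + ["B"] * 45, index=datasets)
        rng = np.random.default_rng(0)
        M = pd.DataFrame(rng.random((n_ds, 60)) < 0.3, index=datasets)
        M[0] = [True] * 5 + [False] * 45
        mm = occupancy_markers(M, biotype)
        assert mm.loc[("chipseq", "A"), 0]

    def test_ubiquitous_consensus_not_marker_for_any_biotype(self):
        datasets = [f"d{i}" for i in range(30)]
        biotype = pd.Series(["A", "B", "C"] * 10, index=datasets)
        M = pd.DataFrame(True, index=datasets, columns=range(5))
        mm = occupancy_markers(M, biotype)
        assert not mm.to_numpy().any()

    def test_pvalues_match_monte_carlo_event_draw_null(self):
        """The implemented null treats the n membership events at a consensus
        as drawn without replacement from the N events across the whole
        matrix (K of which belong to the biotype); check the analytic tail
        against 1e5 Monte-Carlo draws from that event pool."""
        rng = np.random.default_rng(1)
        n_ds, n_cons = 40, 30
        datasets = [f"d{i}" for i in range(n_ds)]
        biotype = pd.Series(["A"] * 10 + ["B"] * 30, index=datasets)
        M = pd.DataFrame(rng.random((n_ds, n_cons)) < 0.3, index=datasets)
        M.iloc[:12, 0] = True  # make region 0 interesting

        Mv = M.to_numpy()
        is_a = (biotype == "A").to_numpy()
        N = int(Mv.sum())
        K = int(Mv[is_a].sum())
        n = int(Mv[:, 0].sum())
        k_obs = int(Mv[is_a, 0].sum())
        from scipy import stats
        p_model = float(stats.hypergeom.sf(k_obs - 1, N, K, n))

        event_is_a = np.repeat(is_a, Mv.sum(axis=1))  # one label per event
        n_draws = 100000
        hits = 0
        for _ in range(n_draws):
            draw = rng.choice(N, size=n, replace=False)
            if event_is_a[draw].sum() >= k_obs:
                hits += 1
        p_mc = hits / n_draws
        se = np.sqrt(max(p_model * (1 - p_model), 1e-8) / n_draws)
        assert abs(p_mc - p_model) <= 3 * max(se, 1e-4)

    def test_unlabelled_dataset_rejected(self):
        M = pd.DataFrame([[True]], index=["d0"])
        with pytest.raises(KeyError):
            occupancy_markers(M, pd.Series({"other": "A"}))


class TestDifferentialRegions:
    @pytest.fixture(scope="class")
    def tumor_data(self):
        cfg = SimConfig(seed=500, n_samples_per_biotype=30,
                        effect_log2fc=-1.5, marker_fraction=0.2)
        counts, meta, truth = simulate_count_matrix(
            [f"r{i:04d}" for i in range(300)], cfg,
            sample_biotypes=["normal", "tumor"])
        counts, sf, res = run_transform(counts)
        condition = meta.set_index("sample_id")["biotype"]
        return counts, sf, res, condition, truth

    def test_planted_downregulated_region_reported_negative(self, tumor_data):
        counts, sf, res, condition, truth = tumor_data
        planted = [r for r, b in truth.items()
                   if b == "tumor" and r in counts.index]
        out = differential_regions(res, counts, condition, sf)
        hits = out.loc[planted]
        assert hits["significant"].mean() >= 0.9
        assert (hits.loc[hits["significant"], "sign"] == -1).all()

    def test_label_swap_flips_signs(self, tumor_data):
        counts, sf, res, condition, _ = tumor_data
        a = differential_regions(res, counts, condition, sf,
                                 positive_class="tumor")
        b = differential_regions(res, counts, condition, sf,
                                 positive_class="normal")
        flip = (a["log2fc"] != 0) | (b["log2fc"] != 0)
        assert np.allclose(a.loc[flip, "log2fc"], -b.loc[flip, "log2fc"])

    def test_identical_groups_few_calls(self):
        cfg = SimConfig(seed=501, n_samples_per_biotype=25, effect_log2fc=0.0)
        counts, meta, _ = simulate_count_matrix(
            [f"r{i:04d}" for i in range(400)], cfg,
            sample_biotypes=["normal", "tumor"])
        counts, sf, res = run_transform(counts)
        condition = meta.set_index("sample_id")["biotype"]
        out = differential_regions(res, counts, condition, sf)
        assert out["significant"].mean() <= 0.075

    def test_non_binary_condition_rejected(self, expression):
        with pytest.raises(ValueError, match="2 conditions"):
            differential_regions(expression["residuals"], expression["counts"],
                                 expression["biotypes"],
                                 expression["size_factors"])


class TestMetaCluster:
    def rows(self, data, labels):
        return pd.DataFrame(np.asarray(data, dtype=bool),
                            index=pd.MultiIndex.from_tuples(labels,
                                                            names=["source", "biotype"]))

    def test_identical_rows_distance_zero_and_merge_first(self):
        m = self.rows([[1, 0, 1, 0, 1, 0], [1, 0, 1, 0, 1, 0],
                       [0, 1, 0, 1, 0, 1]],
                      [("a", "x"), ("b", "x"), ("a", "y")])
        D, Z = meta_cluster(m, max_frac=1.0, min_rows=1)
        assert D.iloc[0, 1] == 0.0
        first_merge = sorted(Z[0, :2].astype(int).tolist())
        assert first_merge == [0, 1]

    def test_complementary_rows_distance_two(self):
        m = self.rows([[1, 0, 1, 0], [0, 1, 0, 1]], [("a", "x"), ("b", "y")])
        D = yule_distance_matrix(m)
        assert D.iloc[0, 1] == pytest.approx(2.0)

    def test_frequency_filters_applied(self):
        # region 0 marker everywhere (dropped), region 1 marker once (dropped)
        m = self.rows([[1, 1, 1, 0], [1, 0, 1, 1], [1, 0, 0, 1]],
                      [("a", "x"), ("b", "x"), ("c", "y")])
        D, _ = meta_cluster(m, max_frac=0.9, min_rows=2)
        # kept columns: those with 2 <= count <= 0.9*3
        assert D.shape == (3, 3)

    def test_all_regions_dropped_is_error(self):
        m = self.rows([[1, 1], [1, 1]], [("a", "x"), ("b", "y")])
        with pytest.raises(ValueError, match="dropped"):
            meta_cluster(m, max_frac=0.4, min_rows=2)

    def test_matching_biotypes_closer_across_sources(self):
        rng = np.random.default_rng(2)
        biotypes = ["b1", "b2", "b3", "b4"]
        n_regions = 400
        blocks = {b: (rng.random(n_regions) < 0.15) for b in biotypes}
        rows, labels = [], []
        for source in ("chip", "rna"):
            for b in biotypes:
                noise = rng.random(n_regions) < 0.03
                rows.append(blocks[b] ^ noise)
                labels.append((source, b))
        m = self.rows(rows, labels)
        D, _ = meta_cluster(m, max_frac=0.9, min_rows=1)
        match, nonmatch, p = matching_vs_nonmatching(D)
        assert match.mean() < nonmatch.mean()
        assert p < 0.01


class TestPancancerThreshold:
    def test_planted_shared_markers_fully_recovered(self):
        rng = np.random.default_rng(3)
        universe = [f"r{i}" for i in range(10000)]
        shared = universe[:100]
        marker_sets = {}
        for c in range(8):
            own = rng.choice(universe[100:], size=400, replace=False).tolist()
            marker_sets[f"cancer{c}"] = set(shared) | set(own)
        out = pancancer_threshold(marker_sets, universe, seed=0)
        assert out["threshold"] <= 8
        assert set(shared) <= set(out["regions"])

    def test_self_null_yields_near_empty_calls(self):
        for seed in range(5):
            rng = np.random.default_rng(600 + seed)
            universe = [f"r{i}" for i in range(5000)]
            marker_sets = {
                f"cancer{c}": set(rng.choice(universe, size=300, replace=False))
                for c in range(8)}
            out = pancancer_threshold(marker_sets, universe, seed=seed)
            n_obs_tail = (out["observed_counts"] >= 1).sum()
            assert len(out["regions"]) <= max(0.05 * n_obs_tail, 2)

    def test_single_cancer_rejected(self):
        with pytest.raises(ValueError, match="2 cancers"):
            pancancer_threshold({"only": {"r1"}}, ["r1", "r2"])

    def test_null_draws_preserve_per_cancer_counts(self):
        universe = [f"r{i}" for i in range(50)]
        marker_sets = {"a": set(universe[:7]), "b": set(universe[5:17])}
        out = pancancer_threshold(marker_sets, universe, n_iter=10, seed=1)
        # total null membership mass equals total observed mass (7 + 12)
        total_null = out["null_tail_mean"][1]  # E[#regions with count >= 1] <= 19
        assert total_null <= 19 + 1e-9
        assert out["observed_counts"].sum() == 19
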