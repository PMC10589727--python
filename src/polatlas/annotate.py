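"""Biotype contribution scores, consensus categories and enrichment tests.

The biotype score machinery turns the boolean occupancy matrix M into
per-consensus biotype proportions that are robust to unbalanced biotype
representation: the raw contribution of biotype i at consensus j is first
normalized by biotype i's total contribution across all consensus, so a
biotype with many datasets (or peak-rich datasets) cannot dominate every
consensus. The Gini-Simpson index of the resulting proportions quantifies
how biotype-specific a consensus is (0 = one biotype only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import IntervalSet, intersect_centroids

CATEGORY_ORDER = ["Promoter-like", "LNC-body", "Enhancer-like",
                  "Regulatory-like", "Gene-tail", "Unannotated"]


@dataclass
class BiotypeScores:
    """Per-consensus biotype contributions.

    s : biotypes x consensus raw contribution (sum over the biotype's
        datasets of the boolean occupancy column).
    n : s row-normalized by each biotype's total across consensus.
    p : per-consensus proportions of n (columns sum to 1 where defined).
    lam : Gini-Simpson index 1 - sum_i p_ij^2 (NaN for all-zero columns).
    dominant : biotype with the largest n at each consensus.
    """

    s: pd.DataFrame
    n: pd.DataFrame
    p: pd.DataFrame
    lam: pd.Series
    dominant: pd.Series


def biotype_scores(M: pd.DataFrame, datasets: pd.DataFrame,
                   peak_counts: pd.DataFrame | None = None) -> BiotypeScores:
    """Aggregate the occupancy matrix per biotype.

    Parameters
    ----------
    M : boolean datasets x consensus occupancy matrix.
    datasets : DataFrame with ``dataset_id`` and ``biotype`` covering every
        row of M.
    peak_counts : optional datasets x consensus *peak-count* matrix; when
        given, raw contributions use the counts instead of the boolean M.
    """
    lookup = datasets.set_index("dataset_id")["biotype"]
    missing = [d for d in M.index if d not in lookup.index]
    if missing:
        raise KeyError(f"datasets without biotype: {missing}")
    base = (peak_counts if peak_counts is not None else M).astype(float)
    biotype_of = lookup.loc[M.index]
    s = base.groupby(biotype_of.values).sum()
    s.index.name = "biotype"

    row_tot = s.sum(axis=1)
    n = s.div(row_tot.replace(0, np.nan), axis=0).fillna(0.0)
    col_tot = n.sum(axis=0)
    p = n.div(col_tot.where(col_tot > 0), axis=1)
    lam = 1.0 - (p ** 2).sum(axis=0, skipna=False)
    empty = M.sum(axis=0) == 0
    lam[empty] = np.nan
    dominant = n.idxmax(axis=0)
    dominant[empty] = np.nan
    return BiotypeScores(s=s, n=n, p=p, lam=lam, dominant=dominant)


# ---------------------------------------------------------------------------
# Enrichment tests
# ---------------------------------------------------------------------------

def binomial_overlap_test(k: int, n_trials: int, feature_coverage: float,
                          universe_coverage: float) -> dict:
    """Upper-tail binomial overlap enrichment of a whole-atlas feature.

    The success probability is the feature's base-pair share of the
    (intergenic) universe; the fold change is k / (n p).
    """
    if universe_coverage <= 0:
        raise ValueError("universe_coverage must be positive")
    if feature_coverage > universe_coverage:
        raise ValueError("feature_coverage exceeds universe_coverage")
    p_param = feature_coverage / universe_coverage
    p_value = float(stats.binom.sf(k - 1, n_trials, p_param)) if k > 0 else 1.0
    expected = n_trials * p_param
    fold = float(k / expected) if expected > 0 else np.inf
    return {"test": "binomial", "k": k, "n": n_trials, "p_param": p_param,
            "p_value": p_value, "fold_change": fold}


def hypergeom_subset_test(N: int, K: int, n: int, k: int) -> dict:
    """Upper-tail hypergeometric enrichment P(X >= k), X ~ HG(N, K, n).

    Used for subset-vs-feature overlap (removes the atlas-wide intersection
    bias), occupancy markers and eQTL enrichment. fold = (k/n) / (K/N).
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    p_value = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
    fold = (k / n) / (K / N) if n > 0 and K > 0 else (np.inf if k > 0 else 0.0)
    return {"test": "hypergeometric", "N": N, "K": K, "n": n, "k": k,
            "p_value": p_value, "fold_change": float(fold)}


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# Category cascade
# ---------------------------------------------------------------------------

def classify_consensus(consensus: pd.DataFrame, refsets: dict,
                       genes: pd.DataFrame | None = None,
                       gene_tail_range=(1000, 9000)) -> pd.Series:
    """First-match category per consensus centroid.

    Cascade: Promoter-like -> LNC-body -> Enhancer-like -> Regulatory-like ->
    Gene-tail -> Unannotated. ``refsets`` maps the first four category names
    to an :class:`IntervalSet` (already pooled over their member resources,
    e.g. cCRE PLS + H3K4me3 + FANTOM TSS + LNCipedia promoters for
    Promoter-like). Gene-tail tests whether the centroid lies 1-9 kb
    downstream of a gene end, strand-aware, against ``genes`` (chrom, start,
    end, strand).
    """
    points = list(zip(consensus["chrom"], consensus["centroid"].astype(int)))
    out = pd.Series("Unannotated", index=consensus.index, dtype=object)
    assigned = np.zeros(len(consensus), dtype=bool)
    for cat in ("Promoter-like", "LNC-body", "Enhancer-like", "Regulatory-like"):
        ivs = refsets.get(cat)
        if ivs is None or len(ivs) == 0:
            continue
        hit = intersect_centroids(points, ivs)
        new = hit & ~assigned
        out[new] = cat
        assigned |= hit
    if genes is not None and len(genes) > 0:
        lo, hi = gene_tail_range
        rows = []
        for _, g in genes.iterrows():
            if g["strand"] == "+":
                rows.append((g["chrom"], g["end"] + lo, g["end"] + hi))
            else:
                rows.append((g["chrom"], max(g["start"] - hi, 0),
                             max(g["start"] - lo, 0)))
        tails = IntervalSet.from_dataframe(
            pd.DataFrame(rows, columns=["chrom", "start", "end"]))
        hit = intersect_centroids(points, tails)
        new = hit & ~assigned
        out[new] = "Gene-tail"
    return out


# ---------------------------------------------------------------------------
# Epigenome-state proportions
# ---------------------------------------------------------------------------

def epistate_proportions(in_cluster: pd.Series, state_calls: pd.DataFrame):
    """Chromatin-state composition of a consensus subset vs. the rest.

    Parameters
    ----------
    in_cluster : boolean Series over consensus (the subset of interest).
    state_calls : consensus x epigenome DataFrame of state labels (e.g. the
        15-state ChromHMM vocabulary).

    Returns
    -------
    (proportions, tests): ``proportions`` is indexed by (epigenome, subset
    in {"cluster", "rest"}) with one column per state, rows summing to 1;
    ``tests`` has a paired t statistic and p-value per state across
    epigenomes (empty with a single epigenome).
    """
    in_cluster = in_cluster.astype(bool)
    states = sorted(pd.unique(state_calls.values.ravel()))
    rows = {}
    for epi in state_calls.columns:
        for name, mask in (("cluster", in_cluster), ("rest", ~in_cluster)):
            calls = state_calls.loc[mask, epi]
            frac = calls.value_counts(normalize=True)
            rows[(epi, name)] = [frac.get(s, 0.0) for s in states]
    proportions = pd.DataFrame.from_dict(rows, orient="index", columns=states)
    proportions.index = pd.MultiIndex.from_tuples(proportions.index,
                                                  names=["epigenome", "subset"])
    n_epi = len(state_calls.columns)
    if n_epi < 2:
        return proportions, pd.DataFrame(columns=["t", "p_value"])
    tests = {}
    for s in states:
        a = proportions.xs("cluster", level="subset")[s].to_numpy()
        b = proportions.xs("rest", level="subset")[s].to_numpy()
        if np.allclose(a, b):
            tests[s] = {"t": 0.0, "p_value": 1.0}
        else:
            t, p = stats.ttest_rel(a, b)
            tests[s] = {"t": float(t), "p_value": float(p)}
    return proportions, pd.DataFrame(tests).T[["t", "p_value"]]


# ---------------------------------------------------------------------------
# eQTL enrichment
# ---------------------------------------------------------------------------

def eqtl_enrichment(markers: dict, eqtl_hits: pd.DataFrame,
                    tissue_frac_cap: float = 0.10, min_markers: int = 50):
    """Pairwise (eQTL tissue x marker tissue) hypergeometric enrichment.

    Parameters
    ----------
    markers : tissue -> boolean Series over regions (marker indicator).
    eqtl_hits : regions x tissues boolean DataFrame; entry True when some
        eQTL of that tissue falls inside the (1-kb) region.
    tissue_frac_cap : regions that are eQTL-hit (resp. marker) in more than
        this fraction of tissues are removed as non-tissue-specific.
    min_markers : marker tissues with fewer surviving markers are dropped.

    Returns a DataFrame of p-values indexed by eQTL tissue, columns marker
    tissue (all-1 rows when a tissue has no eQTL hits).
    """
    marker_df = pd.DataFrame(markers).fillna(False).astype(bool)
    regions = eqtl_hits.index.intersection(marker_df.index)
    eqtl_hits = eqtl_hits.loc[regions].astype(bool)
    marker_df = marker_df.loc[regions]

    ubiquitous_eqtl = eqtl_hits.sum(axis=1) > tissue_frac_cap * eqtl_hits.shape[1]
    ubiquitous_marker = marker_df.sum(axis=1) > tissue_frac_cap * marker_df.shape[1]
    keep = ~(ubiquitous_eqtl | ubiquitous_marker)
    eqtl_hits = eqtl_hits.loc[keep]
    marker_df = marker_df.loc[keep]

    counts = marker_df.sum(axis=0)
    marker_df = marker_df[counts.index[counts >= min_markers]]
    N = len(marker_df)
    out = pd.DataFrame(1.0, index=eqtl_hits.columns, columns=marker_df.columns)
    for et in eqtl_hits.columns:
        hit = eqtl_hits[et]
        K = int(hit.sum())
        for mt in marker_df.columns:
            m = marker_df[mt]
            n = int(m.sum())
            k = int((hit & m).sum())
            out.loc[et, mt] = hypergeom_subset_test(N, K, n, k)["p_value"]
    return out
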