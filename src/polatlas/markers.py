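"""Biotype marker calling, differential expression, meta-clustering and the
resampling-based pan-cancer threshold.

Expression markers of a biotype are regions over-expressed in that biotype
versus all other samples (one-sided Welch t-test on Pearson residuals, BH
FDR 5%), with a log2 fold change above 0.25 on normalized counts and
detectability in at least max(10% of the group, 2) group samples. Occupancy
markers use a per-region hypergeometric test on the binary occupancy matrix.
Marker indicator vectors from several sources feed a Yule-distance
average-linkage meta-clustering that tests whether matching biotypes group
together across data sources.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotate import bh_fdr, hypergeom_subset_test

logger = logging.getLogger(__name__)


def _welch_t(group: np.ndarray, rest: np.ndarray, alternative: str):
    """Vectorized Welch t-test along axis 1 (regions x samples blocks)."""
    res = stats.ttest_ind(group, rest, axis=1, equal_var=False,
                          alternative=alternative)
    return res.statistic, res.pvalue


def _log2fc(counts: np.ndarray, size_factors: np.ndarray,
            in_group: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    norm = counts / size_factors[None, :]
    mean_g = norm[:, in_group].mean(axis=1)
    mean_r = norm[:, ~in_group].mean(axis=1)
    return np.log2(mean_g + pseudocount) - np.log2(mean_r + pseudocount)


def _detectable(counts: np.ndarray, in_group: np.ndarray) -> np.ndarray:
    n_group = int(in_group.sum())
    need = max(int(np.ceil(0.10 * n_group)), 2)
    return (counts[:, in_group] >= 1).sum(axis=1) >= need


def expression_markers(residuals: pd.DataFrame, counts: pd.DataFrame,
                       labels: pd.Series, size_factors: pd.Series,
                       source: str = "rnaseq", fdr: float = 0.05,
                       lfc_min: float = 0.25) -> pd.DataFrame:
    """Group-versus-rest over-expression markers for every biotype.

    Returns a boolean MarkerMatrix block: rows are ``(source, biotype)``
    tuples, columns the regions. Groups with fewer than 2 samples are
    skipped with a log message.
    """
    labels = labels.loc[counts.columns]
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    R = residuals.loc[counts.index, counts.columns].to_numpy()
    X = counts.to_numpy()
    rows = {}
    for biotype in sorted(labels.unique()):
        in_group = (labels == biotype).to_numpy()
        if in_group.sum() < 2 or (~in_group).sum() < 2:
            logger.info("skipping biotype %s: fewer than 2 samples", biotype)
            continue
        _, p = _welch_t(R[:, in_group], R[:, ~in_group], "greater")
        q = bh_fdr(np.nan_to_num(p, nan=1.0))
        lfc = _log2fc(X, sf, in_group)
        det = _detectable(X, in_group)
        rows[(source, biotype)] = (q <= fdr) & (lfc > lfc_min) & det
    out = pd.DataFrame.from_dict(rows, orient="index", columns=counts.index)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["source", "biotype"]) \
        if len(out) else out.index
    return out.astype(bool)


def occupancy_markers(M: pd.DataFrame, labels: pd.Series,
                      source: str = "chipseq", fdr: float = 0.05) -> pd.DataFrame:
    """Hypergeometric occupancy markers per biotype from the binary matrix.

    For each consensus and biotype: N = total membership events in M, K =
    membership events of the biotype's datasets, n = datasets bound at the
    consensus, k = biotype datasets bound there. BH FDR applied per biotype.
    """
    missing = [d for d in M.index if d not in labels.index]
    if missing:
        raise KeyError(f"datasets without biotype label: {missing}")
    lab = labels.loc[M.index]
    Mv = M.to_numpy(dtype=bool)
    N = int(Mv.sum())
    col_n = Mv.sum(axis=0)
    rows = {}
    for biotype in sorted(lab.unique()):
        sel = (lab == biotype).to_numpy()
        K = int(Mv[sel].sum())
        col_k = Mv[sel].sum(axis=0)
        p = stats.hypergeom.sf(col_k - 1, N, K, col_n)
        p = np.where(col_k > 0, p, 1.0)
        q = bh_fdr(p)
        rows[(source, biotype)] = q <= fdr
    out = pd.DataFrame.from_dict(rows, orient="index", columns=M.columns)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["source", "biotype"])
    return out.astype(bool)


def differential_regions(residuals: pd.DataFrame, counts: pd.DataFrame,
                         condition: pd.Series, size_factors: pd.Series,
                         positive_class: str = "tumor", fdr: float = 0.05,
                         lfc_min: float = 0.25) -> pd.DataFrame:
    """Two-sided differential regions between two conditions, with sign.

    A region is differential when the two-sided Welch test on residuals
    passes BH FDR, |log2FC| (positive class over the other, on normalized
    counts) exceeds ``lfc_min`` and the region is detectable in either
    class. Returns a DataFrame (p_value, q_value, log2fc, sign, significant).
    """
    condition = condition.loc[counts.columns]
    classes = sorted(condition.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 conditions, got {classes}")
    in_pos = (condition == positive_class).to_numpy()
    if in_pos.sum() < 2 or (~in_pos).sum() < 2:
        raise ValueError("need >= 2 samples per condition")
    sf = size_factors.loc[counts.columns].to_numpy(dtype=float)
    R = residuals.loc[counts.index, counts.columns].to_numpy()
    X = counts.to_numpy()
    _, p = _welch_t(R[:, in_pos], R[:, ~in_pos], "two-sided")
    p = np.nan_to_num(p, nan=1.0)
    q = bh_fdr(p)
    lfc = _log2fc(X, sf, in_pos)
    det = _detectable(X, in_pos) | _detectable(X, ~in_pos)
    sig = (q <= fdr) & (np.abs(lfc) > lfc_min) & det
    return pd.DataFrame({"p_value": p, "q_value": q, "log2fc": lfc,
                         "sign": np.sign(lfc).astype(int),
                         "significant": sig}, index=counts.index)


# ---------------------------------------------------------------------------
# Meta-clustering
# ---------------------------------------------------------------------------

def yule_distance_matrix(markers: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Yule dissimilarity 2*c10*c01 / (c11*c00 + c10*c01).

    0/0 (e.g. identical rows) is defined as 0; complementary rows give 2.
    """
    X = markers.to_numpy(dtype=bool)
    n = len(X)
    Xf = X.astype(float)
    c11 = Xf @ Xf.T
    c10 = Xf @ (1 - Xf).T
    c01 = (1 - Xf) @ Xf.T
    c00 = (1 - Xf) @ (1 - Xf).T
    num = 2.0 * c10 * c01
    den = c11 * c00 + c10 * c01
    with np.errstate(divide="ignore", invalid="ignore"):
        D = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=markers.index, columns=markers.index)


def meta_cluster(markers: pd.DataFrame, max_frac: float = 0.10,
                 min_rows: int = 2):
    """Average-linkage Yule meta-clustering of (source, biotype) marker rows.

    Regions that are markers in more than ``max_frac`` of the rows
    (non-specific) or fewer than ``min_rows`` rows (unreplicated) are
    dropped, then the Yule distance matrix and average-linkage tree over the
    remaining indicators are returned as ``(distance, linkage)``.
    """
    if len(markers) < 2:
        raise ValueError("need at least 2 marker rows")
    col_counts = markers.sum(axis=0)
    keep = (col_counts <= max_frac * len(markers)) & (col_counts >= min_rows)
    filtered = markers.loc[:, keep]
    if filtered.shape[1] == 0:
        raise ValueError("all regions dropped by the marker-frequency filter")
    D = yule_distance_matrix(filtered)
    Z = hierarchy.average(squareform(D.to_numpy(), checks=False))
    return D, Z


def matching_vs_nonmatching(D: pd.DataFrame):
    """Split cross-source pair distances into matching/non-matching biotype.

    Rows must be indexed by (source, biotype). Returns (matching distances,
    non-matching distances, Mann-Whitney one-sided p-value that matching
    pairs are closer).
    """
    idx = list(D.index)
    match, nonmatch = [], []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            (sa, ba), (sb, bb) = idx[a], idx[b]
            if sa == sb:
                continue
            (match if ba == bb else nonmatch).append(D.iloc[a, b])
    if not match or not nonmatch:
        raise ValueError("need both matching and non-matching cross-source pairs")
    stat = stats.mannwhitneyu(match, nonmatch, alternative="less")
    return np.asarray(match), np.asarray(nonmatch), float(stat.pvalue)


# ---------------------------------------------------------------------------
# Pan-cancer threshold
# ---------------------------------------------------------------------------

def pancancer_threshold(marker_sets: dict, universe, n_iter: int = 100,
                        fdr: float = 0.05, seed: int = 0):
    """Resampling threshold for markers shared across many cancers.

    For each cancer, the null draws the observed number of markers uniformly
    (without replacement) from the universe; over ``n_iter`` iterations this
    yields the expected tail of the per-region cancer-count histogram. The
    threshold T is the smallest count at which the expected null tail is
    less than ``fdr`` times the observed tail.

    Returns a dict with keys ``threshold`` (int or inf), ``regions`` (list
    with observed count >= T), ``observed_counts`` (Series), ``null_tail_mean``
    and ``null_tail_se`` (arrays over count values 0..n_cancers).
    """
    cancers = sorted(marker_sets)
    if len(cancers) < 2:
        raise ValueError("need at least 2 cancers")
    universe = list(universe)
    index = {r: i for i, r in enumerate(universe)}
    n_regions = len(universe)
    n_cancers = len(cancers)

    observed = np.zeros(n_regions, dtype=int)
    for c in cancers:
        for r in marker_sets[c]:
            observed[index[r]] += 1

    rng = np.random.default_rng(seed)
    null_tails = np.zeros((n_iter, n_cancers + 1))
    for it in range(n_iter):
        counts = np.zeros(n_regions, dtype=int)
        for c in cancers:
            m = len(marker_sets[c])
            counts[rng.choice(n_regions, size=m, replace=False)] += 1
        hist = np.bincount(counts, minlength=n_cancers + 1)
        null_tails[it] = np.cumsum(hist[::-1])[::-1]

    obs_hist = np.bincount(observed, minlength=n_cancers + 1)
    obs_tail = np.cumsum(obs_hist[::-1])[::-1]
    null_tail_mean = null_tails.mean(axis=0)
    null_tail_se = null_tails.std(axis=0, ddof=1) / np.sqrt(n_iter)

    threshold = np.inf
    for T in range(1, n_cancers + 1):
        if obs_tail[T] > 0 and null_tail_mean[T] / obs_tail[T] < fdr:
            threshold = T
            break
    if np.isinf(threshold):
        logger.warning("no pan-cancer threshold satisfies the FDR bound")
        regions = []
    else:
        regions = [r for r in universe if observed[index[r]] >= threshold]
    return {"threshold": threshold, "regions": regions,
            "observed_counts": pd.Series(observed, index=universe),
            "null_tail_mean": null_tail_mean, "null_tail_se": null_tail_se}
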