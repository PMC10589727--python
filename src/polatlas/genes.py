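"""Region-to-gene assignment by regulatory domains and gene-set NB GLM.

Genes receive GREAT-style regulatory domains (basal 5 kb upstream / 1 kb
downstream of the TSS, extended up to 1 Mb per side but stopping at the
nearest neighboring basal domain). For a subset of consensus regions (e.g.
a cluster or the pan-cancer markers), each gene g has n_g regions of the
whole atlas and k_g subset regions in its domain; a gene set G is enriched
when the NB regression ln(mu_g) = beta0 + beta1 * I[g in G] with offset
ln(E_g) (E_g = n_g K / N, the expected hits) yields beta1 > 0 by a
one-sided Wald test. The offset corrects for the fact that genes with many
atlas regions in their domain collect more subset hits by construction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .annotate import bh_fdr

logger = logging.getLogger(__name__)

MAX_EXTENSION = 1_000_000
BASAL_UP = 5000
BASAL_DOWN = 1000


def regulatory_domains(genes: pd.DataFrame) -> pd.DataFrame:
    """Basal and extended regulatory domains per gene.

    ``genes`` needs columns chrom, start, end, strand, gene_id; the TSS is
    the strand-aware 5' end. Basal = TSS-5kb..TSS+1kb (strand-aware),
    clipped at 0. Extension on each side reaches min(1 Mb, the nearest other
    gene's basal edge) and never shrinks below the basal domain.

    Returns a DataFrame (gene_id, chrom, tss, basal_start, basal_end,
    ext_start, ext_end).
    """
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            tss = int(g["start"])
            b_start, b_end = tss - BASAL_UP, tss + BASAL_DOWN
        else:
            tss = int(g["end"]) - 1
            b_start, b_end = tss - BASAL_DOWN + 1, tss + BASAL_UP + 1
        rows.append({"gene_id": g["gene_id"], "chrom": g["chrom"], "tss": tss,
                     "basal_start": max(b_start, 0), "basal_end": max(b_end, 0)})
    dom = pd.DataFrame(rows)
    dom["ext_start"] = dom["basal_start"] - MAX_EXTENSION
    dom["ext_end"] = dom["basal_end"] + MAX_EXTENSION
    for chrom, grp in dom.groupby("chrom"):
        grp = grp.sort_values("basal_start")
        idx = grp.index.to_numpy()
        for pos, i in enumerate(idx):
            own_s, own_e = dom.at[i, "basal_start"], dom.at[i, "basal_end"]
            left_edges = grp["basal_end"].to_numpy()[:pos]
            right_edges = grp["basal_start"].to_numpy()[pos + 1:]
            left_limit = own_s - MAX_EXTENSION
            if len(left_edges):
                left_limit = max(left_limit, int(left_edges.max()))
            right_limit = own_e + MAX_EXTENSION
            if len(right_edges):
                right_limit = min(right_limit, int(right_edges.min()))
            dom.at[i, "ext_start"] = min(max(left_limit, 0), own_s)
            dom.at[i, "ext_end"] = max(right_limit, own_e)
    dom["ext_start"] = dom["ext_start"].clip(lower=0)
    return dom[["gene_id", "chrom", "tss", "basal_start", "basal_end",
                "ext_start", "ext_end"]]


def count_hits(domains: pd.DataFrame, universe: pd.DataFrame,
               subset_mask: pd.Series) -> pd.DataFrame:
    """Per-gene region counts inside the extended regulatory domain.

    ``universe`` holds all consensus regions (chrom, centroid);
    ``subset_mask`` is a boolean Series over the universe index. Centroids
    (1 bp) are intersected against domains, which may overlap, so a region
    can count for several genes. Returns GeneHitCounts with columns n, k, E
    and attrs K (subset size) and N (universe size).
    """
    subset_mask = subset_mask.astype(bool)
    N = len(universe)
    K = int(subset_mask.sum())
    out = []
    for chrom, grp in domains.groupby("chrom"):
        u = universe[universe["chrom"] == chrom]
        pos = u["centroid"].to_numpy(dtype=np.int64)
        sub = subset_mask.loc[u.index].to_numpy()
        for _, d in grp.iterrows():
            inside = (pos >= d["ext_start"]) & (pos < d["ext_end"])
            n_g = int(inside.sum())
            k_g = int((inside & sub).sum())
            out.append({"gene_id": d["gene_id"], "n": n_g, "k": k_g})
    res = pd.DataFrame(out).set_index("gene_id")
    missing = domains.loc[~domains["gene_id"].isin(res.index), "gene_id"]
    for g in missing:
        res.loc[g] = {"n": 0, "k": 0}
    res["E"] = res["n"] * (K / N if N > 0 else 0.0)
    res.attrs["K"] = K
    res.attrs["N"] = N
    return res


def nb_glm_geneset_test(hit_counts: pd.DataFrame, gene_set,
                        min_genes: int = 4, max_genes: int = 999,
                        additive_e: bool = False) -> dict:
    """One-sided NB GLM Wald test that a gene set attracts excess hits.

    Genes with n = 0 are excluded (undefined log offset). The linear
    predictor is beta0 + beta1 * G with offset ln(E + 1e-8); with
    ``additive_e=True`` the literal additive-E variant (E as a covariate
    instead of an offset) is fitted for comparison. Overdispersion is
    ML-estimated; a Poisson fallback (flagged) handles non-convergence.

    Returns a dict (set_size, beta1, p_value, fold, converged, fallback).
    """
    counts = hit_counts[hit_counts["n"] > 0]
    in_set = counts.index.isin(set(gene_set))
    size = int(in_set.sum())
    if size < min_genes or size > max_genes:
        raise ValueError(f"gene set size {size} outside [{min_genes}, {max_genes}]")
    y = counts["k"].to_numpy(dtype=float)
    G = in_set.astype(float)
    offset = np.log(counts["E"].to_numpy(dtype=float) + 1e-8)
    if additive_e:
        exog = sm.add_constant(np.column_stack([G, counts["E"].to_numpy()]))
        offset_arg = None
    else:
        exog = sm.add_constant(G)
        offset_arg = offset

    fallback = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.NegativeBinomial(y, exog, offset=offset_arg)
            fit = model.fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception:
            converged = False
            fit = None
        if fit is None or not converged or not np.isfinite(fit.bse[1]):
            fallback = True
            logger.info("NB GLM fell back to Poisson for a gene set")
            fit = sm.GLM(y, exog, family=sm.families.Poisson(),
                         offset=offset_arg).fit()
    beta1 = float(fit.params[1])
    se = float(fit.bse[1])
    z = beta1 / se if se > 0 else np.inf * np.sign(beta1)
    p = float(stats.norm.sf(z))
    return {"set_size": size, "beta1": beta1, "se": se, "p_value": p,
            "fold": float(np.exp(beta1)), "converged": not fallback,
            "fallback": fallback}


def geneset_enrichment(hit_counts: pd.DataFrame, gene_sets: dict,
                       min_genes: int = 4, max_genes: int = 999,
                       fdr: float = 0.05) -> pd.DataFrame:
    """Run the NB GLM over a GMT-style dict of gene sets with BH correction."""
    rows = {}
    for name, members in gene_sets.items():
        measured = set(hit_counts.index[hit_counts["n"] > 0])
        size = len(measured & set(members))
        if size < min_genes or size > max_genes:
            continue
        rows[name] = nb_glm_geneset_test(hit_counts, members,
                                         min_genes=min_genes,
                                         max_genes=max_genes)
    out = pd.DataFrame(rows).T
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy(dtype=float))
        out["significant"] = out["q_value"] <= fdr
    return out


def read_gmt(path) -> dict:
    """GMT-like TSV: set name, description, then member gene ids."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(parts[2:])
    return sets


def reduce_terms(term_matrix: pd.DataFrame, p_values: pd.Series,
                 k_neighbors: int = 10, resolution: float = 1.0,
                 seed: int = 0) -> pd.DataFrame:
    """Cluster redundant significant terms and pick one representative each.

    ``term_matrix`` is boolean terms x genes. Terms are joined in a Yule
    k-NN graph, partitioned with Leiden, and each cluster's representative
    is its smallest-p term (ties broken by lexicographic id).

    Returns a DataFrame (cluster, p_value, representative) indexed by term.
    """
    from .markers import yule_distance_matrix
    import igraph
    import leidenalg

    terms = list(term_matrix.index)
    if len(terms) == 1:
        return pd.DataFrame({"cluster": [0], "p_value": [p_values.iloc[0]],
                             "representative": [True]}, index=terms)
    D = yule_distance_matrix(term_matrix).to_numpy()
    k = min(k_neighbors, len(terms) - 1)
    edges = set()
    for i in range(len(terms)):
        order = np.argsort(D[i], kind="stable")
        nbrs = [j for j in order if j != i][:k]
        for j in nbrs:
            edges.add((min(i, j), max(i, j)))
    g = igraph.Graph(n=len(terms), edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    labels = np.asarray(part.membership)
    out = pd.DataFrame({"cluster": labels,
                        "p_value": p_values.loc[terms].to_numpy()},
                       index=terms)
    out["representative"] = False
    for c in np.unique(labels):
        members = out[out["cluster"] == c]
        best = members.sort_values(["p_value"], kind="stable")
        best = best.loc[best["p_value"] == best["p_value"].iloc[0]]
        rep = sorted(best.index)[0]
        out.loc[rep, "representative"] = True
    return out
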