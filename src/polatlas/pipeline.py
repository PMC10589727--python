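"""End-to-end driver: synthetic inputs through atlas, transform and markers.

This is the orchestration layer used by the analysis scripts: it wires the
stage modules together with scale-appropriate parameters and returns every
intermediate product, so recovery of the planted structure (biotype labels,
marker regions, hazard regions) can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate, clustering, consensus, features, genomic_io, markers
from . import simulate, transform


@dataclass
class AtlasResult:
    datasets: pd.DataFrame
    peaks: pd.DataFrame
    consensus: pd.DataFrame
    membership: dict
    M: pd.DataFrame
    scores: annotate.BiotypeScores
    region_biotype: pd.Series  # majority source-locus biotype per consensus


def build_synthetic_atlas(cfg: simulate.SimConfig,
                          min_peaks: int = 20) -> AtlasResult:
    """Simulate peak sets, filter to intergenic space and build the atlas.

    ``min_peaks`` is scaled below the production default of 100 because the
    synthetic datasets emit far fewer intergenic peaks than a real ChIP-seq
    experiment.
    """
    datasets, peaks, truth = simulate.simulate_peak_datasets(cfg)
    transcripts, blacklist = simulate.simulate_annotation(cfg)
    mask = genomic_io.build_intergenic_mask(transcripts, blacklist)
    kept, kept_ds = genomic_io.filter_dataset_peaks(
        peaks, mask, min_peaks=min_peaks, known_chroms=cfg.chrom_names())
    cons, membership = consensus.segment_consensus(kept, consensus.KernelConfig())
    M = consensus.build_occupancy_matrix(cons, membership, kept, kept_ds)
    scores = annotate.biotype_scores(M, datasets)

    locus_bt = truth.set_index("locus_id")["biotype"]
    region_biotype = {}
    for j, members in membership.items():
        loci = kept.loc[members, "locus_id"]
        region_biotype[j] = locus_bt.loc[loci.mode().iloc[0]]
    return AtlasResult(datasets=datasets, peaks=kept, consensus=cons,
                       membership=membership, M=M, scores=scores,
                       region_biotype=pd.Series(region_biotype))


@dataclass
class ExpressionResult:
    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    marker_truth: dict
    size_factors: pd.Series
    model: transform.NBModel
    residuals: pd.DataFrame
    hvr: pd.DataFrame
    n_components: int
    pc_scores: np.ndarray
    sample_biotype: pd.Series


def quantify_expression(atlas: AtlasResult, cfg: simulate.SimConfig,
                        stream: str = "counts") -> ExpressionResult:
    """Simulate counts at the atlas regions and run the residual transform.

    The planted expression markers are the atlas regions themselves, boosted
    in the biotype of their majority source locus — the coupling between
    occupancy and transcription the analysis is designed to detect.
    """
    region_ids = [f"region{j:05d}" for j in atlas.consensus.index]
    region_biotypes = {rid: atlas.region_biotype[j]
                       for rid, j in zip(region_ids, atlas.consensus.index)}
    counts, meta, truth = simulate.simulate_count_matrix(
        region_ids, cfg, region_biotypes=region_biotypes, stream=stream)
    counts = transform.filter_low_counts(counts)
    _, top = transform.detectability_rank(counts)
    sf = transform.pooling_size_factors(counts.loc[top])
    model = transform.fit_regularized_nb(counts, sf, seed=cfg.seed)
    residuals = transform.pearson_residuals(counts, model)
    hvr = features.select_hvr(residuals)
    selected = residuals.loc[hvr["selected"]]
    if selected.shape[0] < 2:
        selected = residuals
    n_comp, scores, _ = features.horn_pca(selected.T.to_numpy(), seed=cfg.seed)
    scores = scores[:, :max(n_comp, 2)]
    biotype = meta.set_index("sample_id")["biotype"].loc[residuals.columns]
    return ExpressionResult(counts=counts, sample_meta=meta,
                            marker_truth=truth, size_factors=sf, model=model,
                            residuals=residuals, hvr=hvr,
                            n_components=n_comp, pc_scores=scores,
                            sample_biotype=biotype)


def cross_source_markers(atlas: AtlasResult,
                         expr: ExpressionResult) -> pd.DataFrame:
    """Stack occupancy (ChIP) and expression (RNA) marker indicator rows
    over the shared region universe."""
    occ = markers.occupancy_markers(
        atlas.M, atlas.datasets.set_index("dataset_id")["biotype"],
        source="chipseq")
    occ.columns = [f"region{j:05d}" for j in occ.columns]
    expr_m = markers.expression_markers(
        expr.residuals, expr.counts, expr.sample_biotype, expr.size_factors,
        source="rnaseq")
    common = [c for c in occ.columns if c in expr_m.columns]
    return pd.concat([occ[common], expr_m[common]])
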