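# polatlas

Tools for building a consensus atlas of **intergenic RNA polymerase II
(RNAPII) binding** from many ChIP-seq peak sets, and for quantifying and
mining **intergenic transcription** at the resulting regions: biotype
markers, cross-resource meta-clustering, pan-cancer differential markers and
survival screening.

Most transcription outside genes happens at enhancers and other regulatory
elements that recruit RNAPII. Rather than chasing the unstable RNA products,
this package aggregates RNAPII occupancy itself: pooling peak sets from
hundreds of experiments across tissues and cell lines identifies recurrent
intergenic binding sites, and RNA-seq read counts at those sites turn out to
carry enough signal to classify tissues, cancer types and subtypes, and to
flag regions whose transcription predicts survival. The package is aimed at
regulatory-genomics analysts who have per-dataset narrowPeak files plus
region×sample count tables and want the full pipeline with testable parts.

## The method

**Consensus regions.** Merging peak intervals across hundreds of datasets
degenerates (the genome becomes one block), so consensus elements are
delimited in summit space: the per-bp histogram of peak summits on each
chromosome is smoothed with a Gaussian kernel (σ = 1/8 of the average peak
width by default) and segmented at the local minima of the smoothed density.
All peaks whose summits fall between two flanking minima form one candidate;
candidates with peaks from ≥ 2 distinct datasets become consensus regions,
with boundaries from the farthest member peaks and centroid at the mean
member summit. A boolean occupancy matrix *M* (datasets × consensus) records
membership. Per-consensus biotype proportions are computed with an
anti-dominance normalization (each biotype's contribution is scaled by its
genome-wide total before forming proportions *p*), summarized by the
Gini–Simpson diversity λ = 1 − Σᵢ pᵢ².

**Expression at regions.** Consensus regions are standardized to 1 kb around
the centroid and treated like genes in an RNA-seq count table. Because these
counts are sparse and the sample count is large, the transform follows the
single-cell playbook: pooled/deconvolved size factors computed on the top-5%
most *detectable* regions, a per-region negative-binomial model
ln μ = β₀ + ln s with variance μ + αμ², a 20-bin mean–overdispersion trend
(modal α per bin by KDE) for regularization, and clipped Pearson residuals
r = (x − μ)/√(μ + αμ²) with clip bound √(9 + n/4).

**Mining.** Highly variable regions are selected by a χ²(n−1) test on
Σ r² with BH FDR; PCA dimensionality comes from Horn's permutation parallel
analysis; samples and regions are clustered with shared-nearest-neighbor
Leiden graphs. Markers per biotype come from one-sided Welch tests on
residuals (expression) or per-region hypergeometric tests on *M*
(occupancy); marker indicator vectors from different data sources are
meta-clustered under Yule dissimilarity. Regions differential in "more
cancers than chance allows" are found with a resampling null that redraws
each cancer's marker count uniformly; prognostic regions come from
univariate Cox screens on residuals with maximally-selected log-rank
cutpoints for display.

All inputs can be simulated (`polatlas.simulate`) with planted ground truth
— biotype-specific source loci with summit jitter, NB counts with
library-size variation and biotype/tumor effects, proportional-hazards
survival — so every stage is testable end to end without downloads.

## Worked example

```python
from polatlas.simulate import SimConfig
from polatlas import pipeline, clustering, features, markers
from sklearn.metrics import adjusted_rand_score

cfg = SimConfig(seed=1, n_biotypes=6)          # 30 datasets, 300 source loci
atlas = pipeline.build_synthetic_atlas(cfg)    # peaks -> filters -> consensus
expr = pipeline.quantify_expression(atlas, cfg)  # counts -> residuals -> PCA

labels = clustering.snn_leiden(expr.pc_scores, k_neighbors=15, seed=0)
ari = adjusted_rand_score(expr.sample_biotype.to_numpy(), labels)
acc = features.classify_balanced(expr.pc_scores,
                                 expr.sample_biotype.to_numpy(),
                                 folds=5, seed=0)
rows = pipeline.cross_source_markers(atlas, expr)
D, _ = markers.meta_cluster(rows, max_frac=0.34, min_rows=2)
match, nonmatch, p = markers.matching_vs_nonmatching(D)
```

Output:

```
consensus regions: 300
mean width: 497.8 bp
mean datasets/consensus: 6.61
highly variable regions: 258 of 300
principal components retained: 6
SNN-Leiden clusters: 6, ARI vs planted biotypes: 1.00
balanced accuracy (KNN, 5-fold): 1.00
meta-clustering: matching Yule distance 0.00, non-matching 2.00, Mann-Whitney p = 2.0e-09
```

The 300 planted source loci are recovered as 300 consensus regions of ~500 bp
supported by ~6.6 datasets each; unsupervised clustering of the RNA samples
reproduces the 6 planted biotypes exactly; and marker sets derived
independently from ChIP occupancy and from RNA expression agree when — and
only when — they describe the same biotype (matching pairs at Yule distance
0 versus 2 for non-matching pairs).

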