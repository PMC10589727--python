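# Methods

This note records the models implemented by `polatlas`, the parameters that
matter, the numerical decisions taken where the design was genuinely open,
and what the synthetic data does and does not establish.

## Consensus segmentation

Peak summits on one chromosome are binned at 1 bp and convolved with a
Gaussian kernel truncated at ±4σ and renormalized, so the density integrates
to the summit count. The grid is restricted to the summit span ±4σ. Summits
are partitioned at the local minima of the discrete density; a run of equal
values counts as a minimum when the values immediately before and after the
run are both strictly larger, and the cut is placed at the leftmost grid
point of the run (a deterministic plateau tie-break). A summit sitting
exactly on a cut belongs to the right-hand segment. Candidates need peaks
from at least `min_datasets = 2` distinct datasets, applied before boundary
computation. Boundaries are the min start / max end of member peaks; the
centroid is the mean member-summit position, kept as a float internally and
rounded half-to-even for BED output. The default σ is 1/8 of the average
peak width, computed genome-wide over the post-filter intergenic peaks.
These conventions are locked by an exact-equivalence test against a
brute-force per-bp kernel-sum oracle (50 random instances up to 1,000
summits).

Intergenic space is defined by exclusion: transcripts padded ±1 kb plus the
blacklist, merged; a peak overlapping the exclusion mask by ≥ 1 bp is
removed (whole interval, not just the summit), peaks need −log10 q > 5
(q < 1e−5, compared on the −log10 scale to avoid underflow), and datasets
with fewer than 100 surviving intergenic peaks are dropped (scaled to 20 in
the synthetic driver, whose datasets emit ~150 peaks rather than thousands).
Consensus-versus-feature intersections afterwards use the 1-bp centroid
only.

## Biotype scores

With boolean occupancy matrix *M* and biotype sets *aᵢ*:
s_{i,j} = Σ_{k∈aᵢ} M_{k,j}, n_{i,j} = s_{i,j}/Σ_{j'} s_{i,j'},
p_{i,j} = n_{i,j}/Σ_{i'} n_{i',j}, λ_j = 1 − Σᵢ p_{i,j}². The row
normalization prevents biotypes with many datasets or peak-rich datasets
from dominating every consensus; duplicating all datasets of one biotype
leaves n (hence the dominant label and λ) unchanged, which is tested. The
raw contribution can optionally be computed from per-dataset peak *counts*
instead of boolean membership (`peak_counts=` argument); boolean is the
default because M is defined as binary. All-zero columns give λ = NaN and a
missing dominant label.

## Count transform

Filtering keeps regions with ≥ 1 read in ≥ 3 samples. Detectability ranks
regions by the number of samples with ≥ 1 read, with ties broken at ≥ 2 …
≥ 5 reads and finally by region id (deterministic); the top 5% (ceiling)
feed the size-factor estimation. Size factors use ring pooling: samples
ordered by library size on a ring, pools of sizes {11, 21, 31} (those that
fit the sample count; a single odd fallback size below 11 samples), one
median pool-vs-average-profile ratio per pool, and a least-squares solve
with low-weight (0.01) anchor equations tying each factor to its relative
library size to keep the system full rank. Factors are rescaled to mean 1;
a non-positive solution triggers a logged median-of-ratios fallback on the
same subset.

Each region gets an NB intercept model ln μ = β₀ + ln s fitted by
Nelder–Mead over (β₀, ln α) on the exact NB log-likelihood, initialized at
the closed-form Poisson intercept and a moment estimate of α. Up to 5,000
randomly chosen regions (seeded) supply the regularization trend: regions
binned into 20 quantile-of-log-mean groups, modal α per bin from a Gaussian
KDE (Silverman bandwidth) on ln α, bin centers at the mean log-mean, linear
interpolation between centers and flat extrapolation beyond. The trend α is
re-assigned to **all** regions (regularization semantics), including the
ones whose own fit converged. Residuals r = (x − μ)/√(μ + αμ²) are clipped
at c = √(9 + n/4): the constant loosens the bound at small sample sizes
without changing large-n behavior, and the bound is configurable. On
simulated NB data (2,000 × 200, α(μ) = 0.2 + 4/μ) the trend is recovered
within 20% in every bin and residuals are standardized (tested).

A practical caveat the tests surface: when the region universe is small, the
top-5% pooling subset is only a handful of regions, and planted
group-specific effects inside it visibly distort the factors. At realistic
region counts the median is robust; the marker power tests therefore use
≥ 1,000 regions.

## Feature selection, PCA, classification

Highly variable regions: T = Σ_s r² compared to χ² with n − 1 degrees of
freedom (intercept model, p = 1), upper tail, BH FDR 5%.

Horn's parallel analysis permutes each feature's values independently
across samples (3 permutations) and compares the real eigenvalues against
the **largest** mean permuted eigenvalue (the noise ceiling), retaining
components contiguously until the first failure. A rank-matched comparison
(real λᵢ vs permuted λᵢ) is a coin flip at the random-matrix bulk edge and
retains spurious components on pure noise; the ceiling comparison keeps the
count at 0–1 for noise and still recovers planted components exactly, which
is what the tests require. PCA uses the randomized solver, seeded.

Classification reports balanced accuracy (mean per-class recall) over
stratified k-fold CV with pooled out-of-fold predictions, `knn` or `gbt`
(histogram gradient boosting with balanced sample weights); fold counts
shrink with a warning when the smallest class is too small.

## Clustering

Heatmap ordering: UMAP to 10 dimensions under the requested metric (Yule,
Sørensen–Dice, Pearson correlation or Euclidean), k-means compression to
50,000 centroids only above that size, Ward linkage on centroids, items
ordered by dendrogram leaves. Cluster discovery: exact k-NN below 5,000
items (approximate NN-descent above, when available), SNN edge weights =
shared-neighbor counts, Leiden with modularity (RBConfiguration) at
resolution 1.0 (exposed), seeded. Cluster count is data-driven.

## Markers, meta-clustering, pan-cancer threshold

Expression markers per biotype: one-sided Welch t-test (group > rest) on
residuals with BH FDR 5% per biotype, log2 fold change > 0.25 on
size-factor-normalized mean counts with pseudocount 1, and detectability
(≥ 1 read) in ≥ max(10% of the group, 2) group samples; all three required.
Welch rather than pooled-variance is a deliberate choice. Differential
regions between two conditions use the two-sided version with |log2FC| and
detectability in either class, reporting the sign.

Occupancy markers: per (region, biotype) hypergeometric upper tail with
N = total membership events in M, K = events of the biotype's datasets,
n = datasets bound at the region, k = biotype datasets bound there; BH per
biotype. The analytic tail is checked against a 10⁵-draw Monte-Carlo from
the event pool.

Meta-clustering stacks (source, biotype) marker indicator rows, drops
regions marker in more than `max_frac` of rows or fewer than 2 rows, and
clusters rows by average linkage under Yule dissimilarity
d = 2·c₁₀·c₀₁/(c₁₁·c₀₀ + c₁₀·c₀₁) with 0/0 defined as 0 (identical rows)
and complementary rows at the maximum 2. `max_frac` must scale with the row
count: the production default 0.10 assumes dozens of (source, biotype)
rows; with 12 rows (2 sources × 6 biotypes) the synthetic analyses use 0.34
so that a marker shared by one matching cross-source pair is not discarded
as "ubiquitous".

The pan-cancer threshold redraws, for each cancer, its observed marker
count uniformly without replacement from the region universe (independent
across cancers and 100 iterations), forms the null tail of the per-region
cancer-count histogram, and sets T to the smallest count where mean null
tail / observed tail < 5% (≥ at T, matching "in more cancers than
expected"). No qualifying T yields T = ∞ and an empty, flagged result.

## Survival

Per-region univariate Cox proportional-hazards fits on residuals (lifelines,
Efron ties — the tie method was unstated and Efron is the accurate default),
Wald p-values, BH FDR 5%; constant covariates and failed fits are skipped
and excluded from the correction. The maximally selected log-rank cutpoint
scans unique expression values inside the 10–90% quantile range and
estimates the selection-corrected p-value by permuting expression labels
(default 10,000, configurable; an add-one Monte-Carlo estimate). This is a
permutation stand-in for the exact conditional Monte-Carlo method used by
dedicated maxstat implementations — unbiased under the null but with
resolution limited to 1/(n_perm + 1).

## Gene-set enrichment

Regulatory domains follow the GREAT heuristic: basal = TSS − 5 kb to
TSS + 1 kb strand-aware (gene-level TSS, 5′-most), extended per side to
min(1 Mb, nearest other basal edge), never below basal. For subset K of N
atlas regions, gene g with n_g domain regions and k_g subset regions has
expected hits E_g = n_g·K/N; the gene-set test is an NB regression
k ~ β₀ + β₁·G with offset ln(E + 1e−8), one-sided Wald on β₁ > 0,
ML-estimated overdispersion (statsmodels) and a flagged Poisson fallback on
non-convergence. The "+E" term is implemented as a log offset because its
stated role is correcting expected-hit bias, which is exposure semantics;
the literal additive-E covariate variant is available behind
`additive_e=True` for comparison. Genes with n_g = 0 are excluded (the log
offset is undefined). Sets are kept with > 3 and < 1,000 measured member
genes; BH across sets. Redundant significant terms are reduced with a Yule
k-NN graph + Leiden, representative = smallest p (lexicographic ties).

FDR convention package-wide: Benjamini–Hochberg within each named analysis
batch.

## Synthetic data

The generators are pure functions of a config whose single seed is expanded
into independent CRC-keyed streams, so adding a generator never shifts
another's draws. Ground truth (locus biotypes, marker regions, hazard
regions) is always returned.

Defaults describe a desk-scale version of the data regime: 2 chromosomes of
1 Mb, 300 source loci in a reserved intergenic zone, 30 datasets × 150
peaks of ~400 bp (halfwidth 200) with 30 bp summit jitter and 10% of peaks
failing the q-filter; 6 biotypes × 30 RNA samples with NB counts (base
means 5–50, overdispersion 0.3, lognormal library sizes with σ = 0.3) and a
2-unit log2 biotype effect at planted marker regions; exponential survival
with baseline hazard 10⁻³/day, log hazard ratio 1 per unit residual at
planted regions and 30% independent censoring. Gene models (2–10 kb,
≥ 2.5 kb gaps) and a ~1% blacklist occupy the genic zone, separated from
the locus zone by a margin larger than the transcript padding plus peak
halfwidth, so planted loci are intergenic by construction.

What the synthetic data does **not** emulate: genomic sequence and
mappability, overlapping/nested gene structure, peaks inside genic space
that the mask must remove (the filters are exercised by the q-value and
blacklist paths and by unit tests instead), read-level sampling
(counts are generated at regions directly), correlated biotypes, and batch
effects between sources. Passing tests therefore demonstrate correctness of
the algorithms under their stated models, not robustness to the full
messiness of public ChIP-seq/RNA-seq compendia.

## Problem sizes

The test suite and the acceptance script run at deliberately small scale —
hundreds of regions, tens of datasets, ≤ 360 samples, 8 synthetic cancers,
50 oracle instances up to 1,000 summits — chosen so the full suite
completes in a few minutes on one CPU while every statistical check retains
enough power to be meaningful at its stated tolerance.
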