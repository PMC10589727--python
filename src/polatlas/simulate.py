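"""Synthetic data with the statistical structure the pipeline assumes.

The generators emulate the regimes of the real inputs: many ChIP-seq peak
sets whose summits jitter around shared biotype-specific "source loci"
placed in a reserved intergenic zone, negative-binomial read counts with
library-size variation and biotype/tumor effects, proportional-hazards
survival times linked to planted regions, and per-base coverage profiles of
the two observed shapes (narrow bump vs. 1-kb plateau). Every generator is a
pure function of its configuration: the single global seed is expanded into
independent named streams so adding one generator never shifts the draws of
another. Ground truth (locus biotypes, marker regions, hazard regions) is
always returned alongside the data so recovery can be tested.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import IntervalSet, write_narrowpeak, write_bed, write_gff3_transcripts

BIOTYPES = ["blood", "brain", "liver", "lung", "digestive", "breast",
            "kidney", "skin", "muscle", "heart", "pancreas", "prostate",
            "ovary", "thyroid", "embryonic", "bone"]


@dataclass
class SimConfig:
    """Study-condition parameters for all generators.

    Defaults describe a desk-scale version of the real data regime: ~400-bp
    peaks (halfwidth 200) with ~30-bp summit jitter, NB counts with
    overdispersion 0.3 and ~35% lognormal library-size spread, and a 2-fold
    (log2) biotype expression effect.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_biotypes: int = 6
    n_source_loci: int = 300
    loci_biotype_specificity: float = 0.8
    n_datasets: int = 30
    peaks_per_dataset: int = 150
    summit_jitter_sd: float = 30.0
    peak_halfwidth: int = 200
    n_samples_per_biotype: int = 30
    nb_mean_range: tuple = (5.0, 50.0)
    nb_overdispersion: float = 0.3
    libsize_lognormal_sd: float = 0.3
    effect_log2fc: float = 2.0
    n_survival_regions: int = 1
    hazard_log_hr: float = 1.0
    # ancillary knobs
    q_fail_fraction: float = 0.1      # fraction of peaks failing the q<1e-5 filter
    blacklist_fraction: float = 0.01  # fraction of genome covered by blacklist
    n_genes_per_chrom: int = 30
    marker_fraction: float = 0.05     # per-biotype planted marker regions
    censoring_rate: float = 0.3
    baseline_hazard: float = 1e-3     # events per day at linear predictor 0

    def __post_init__(self):
        counts = [self.n_chromosomes, self.n_biotypes, self.n_source_loci,
                  self.n_datasets, self.peaks_per_dataset,
                  self.n_samples_per_biotype, self.n_survival_regions]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        for p in (self.loci_biotype_specificity, self.q_fail_fraction,
                  self.blacklist_fraction, self.censoring_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.chrom_length <= 2 * self.peak_halfwidth:
            raise ValueError("chrom_length must exceed 2 * peak_halfwidth")
        if self.nb_overdispersion < 0 or self.libsize_lognormal_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        lo, hi = self.nb_mean_range
        if lo <= 0 or hi < lo:
            raise ValueError("nb_mean_range must be positive and ordered")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent per-generator stream derived from the global seed.

        The stream name enters through a stable CRC32 key (Python's ``hash``
        is salted per process and would break reproducibility).
        """
        key = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        ss = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return np.random.default_rng(ss)

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_sizes(self):
        return {c: self.chrom_length for c in self.chrom_names()}

    def biotype_names(self):
        return BIOTYPES[: self.n_biotypes] if self.n_biotypes <= len(BIOTYPES) else [
            f"biotype{i}" for i in range(self.n_biotypes)]


# ---------------------------------------------------------------------------
# Genome layout
# ---------------------------------------------------------------------------
# Each chromosome is split into a genic zone [0, 0.55 L) holding gene models
# and blacklist blocks, a buffer, and a reserved intergenic zone
# [0.6 L + margin, L - margin) holding the source loci. The margin keeps
# peaks (and the 1-kb transcript padding) from ever crossing zones.

_GENIC_FRAC = 0.55
_ZONE_FRAC = 0.60


def _zone_bounds(cfg: SimConfig):
    margin = 2000 + cfg.peak_halfwidth
    lo = int(_ZONE_FRAC * cfg.chrom_length) + margin
    hi = cfg.chrom_length - margin
    return lo, hi


def simulate_annotation(cfg: SimConfig):
    """Non-overlapping gene models away from the reserved zone + blacklist.

    Returns ``(transcripts, blacklist)`` as :class:`IntervalSet` (transcripts
    carry strand). The blacklist tiles ~``blacklist_fraction`` of the genome
    inside the genic zone.
    """
    rng = cfg.rng("annotation")
    t_rows, b_rows = [], []
    genic_end = int(_GENIC_FRAC * cfg.chrom_length)
    for chrom in cfg.chrom_names():
        # genes: random lengths 2-10 kb laid left to right with >=2.5 kb gaps
        pos = 1000
        for _ in range(cfg.n_genes_per_chrom):
            length = int(rng.integers(2000, 10001))
            gap = int(rng.integers(2500, 6001))
            if pos + length > genic_end - 1000:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            t_rows.append((chrom, pos, pos + length, strand))
            pos += length + gap
        # blacklist: 2-kb tiles evenly spread over the genic zone
        target = cfg.blacklist_fraction * cfg.chrom_length
        n_blocks = int(np.round(target / 2000))
        if n_blocks > 0:
            anchors = np.linspace(0, genic_end - 2000, n_blocks).astype(int)
            for a in anchors:
                b_rows.append((chrom, int(a), int(a) + 2000))
    transcripts = IntervalSet.from_dataframe(
        pd.DataFrame(t_rows, columns=["chrom", "start", "end", "strand"]))
    blacklist = IntervalSet.from_dataframe(
        pd.DataFrame(b_rows, columns=["chrom", "start", "end"]))
    return transcripts, blacklist


def simulate_gene_table(cfg: SimConfig) -> pd.DataFrame:
    """Gene-level table (chrom, start, end, strand, gene_id) matching
    :func:`simulate_annotation`'s transcripts (one transcript per gene)."""
    transcripts, _ = simulate_annotation(cfg)
    df = transcripts.to_dataframe()
    df["gene_id"] = [f"gene{i}" for i in range(len(df))]
    return df


# ---------------------------------------------------------------------------
# Peak sets
# ---------------------------------------------------------------------------

def simulate_peak_datasets(cfg: SimConfig):
    """Per-dataset peak sets anchored on shared biotype-labelled source loci.

    Each dataset is assigned a biotype (round-robin). For each of its peaks
    a source locus is chosen: with probability ``loci_biotype_specificity``
    uniformly among loci of the dataset's own biotype, otherwise uniformly
    among all loci. The summit is the locus position plus rounded Gaussian
    jitter, the interval is summit +- halfwidth clipped to the chromosome,
    and a ``q_fail_fraction`` of peaks draw a -log10 q-value below 5.

    Returns ``(datasets, peaks, truth)`` where ``truth`` is a DataFrame of
    loci (locus_id, chrom, pos, biotype).
    """
    if cfg.n_source_loci > 0 and cfg.peaks_per_dataset > cfg.n_source_loci * 10:
        raise ValueError("peaks_per_dataset > 10x n_source_loci: degenerate "
                         "oversampling of source loci")
    rng = cfg.rng("peaks")
    biotypes = cfg.biotype_names()
    chroms = cfg.chrom_names()

    # place loci in the reserved zone, spaced >= 4 kb so regions are resolvable
    lo, hi = _zone_bounds(cfg)
    loci = []
    if cfg.n_chromosomes > 0 and cfg.n_source_loci > 0:
        per_chrom = np.array_split(np.arange(cfg.n_source_loci), cfg.n_chromosomes)
        for chrom, ids in zip(chroms, per_chrom):
            if len(ids) == 0:
                continue
            positions = np.linspace(lo, hi, len(ids) + 2)[1:-1].astype(int)
            for locus_id, pos in zip(ids, positions):
                loci.append({"locus_id": int(locus_id), "chrom": chrom,
                             "pos": int(pos),
                             "biotype": biotypes[int(rng.integers(len(biotypes)))]
                             if biotypes else "none"})
    truth = pd.DataFrame(loci, columns=["locus_id", "chrom", "pos", "biotype"])

    datasets = []
    peak_rows = []
    for d in range(cfg.n_datasets):
        biotype = biotypes[d % len(biotypes)] if biotypes else "none"
        ds_id = f"ds{d:03d}.{biotype}"
        datasets.append({"dataset_id": ds_id, "biotype": biotype})
        if len(truth) == 0:
            continue
        own = truth.index[truth["biotype"] == biotype].to_numpy()
        for _ in range(cfg.peaks_per_dataset):
            if len(own) > 0 and rng.random() < cfg.loci_biotype_specificity:
                locus = truth.iloc[int(rng.choice(own))]
            else:
                locus = truth.iloc[int(rng.integers(len(truth)))]
            summit = int(locus["pos"] + np.round(rng.normal(0, cfg.summit_jitter_sd)))
            summit = int(np.clip(summit, 1, cfg.chrom_length - 2))
            start = max(summit - cfg.peak_halfwidth, 0)
            end = min(summit + cfg.peak_halfwidth, cfg.chrom_length)
            if rng.random() < cfg.q_fail_fraction:
                qvalue = float(rng.uniform(1.0, 5.0))     # fails q < 1e-5
            else:
                qvalue = float(rng.uniform(6.0, 30.0))
            peak_rows.append({"chrom": locus["chrom"], "start": start,
                              "end": end, "summit": summit, "qvalue": qvalue,
                              "dataset_id": ds_id,
                              "locus_id": int(locus["locus_id"])})
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "summit",
                                             "qvalue", "dataset_id", "locus_id"])
    datasets = pd.DataFrame(datasets, columns=["dataset_id", "biotype"])
    return datasets, peaks, truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def simulate_count_matrix(regions, cfg: SimConfig, region_biotypes=None,
                          sample_biotypes=None, condition: str = "normal",
                          stream: str = "counts"):
    """NB counts at regions with library-size and biotype-marker effects.

    counts[r, s] ~ NB(mean = base_r * libsize_s * 2^(effect_log2fc * I[r is a
    marker for biotype(s)]), variance = mu + alpha mu^2).

    Parameters
    ----------
    regions : sequence of region identifiers (>= 1).
    region_biotypes : optional mapping region -> biotype declaring the planted
        markers; when None, a ``marker_fraction`` per biotype is drawn at
        random (disjoint across biotypes).
    sample_biotypes : optional explicit list of biotype labels to simulate
        (default: ``cfg.biotype_names()``), ``n_samples_per_biotype`` each.

    Returns ``(counts, sample_meta, marker_truth)``: counts is a regions x
    samples integer DataFrame, sample_meta has (sample_id, biotype,
    condition, libsize_factor), marker_truth maps region -> biotype (planted
    markers only).
    """
    regions = list(regions)
    if len(regions) == 0:
        meta = pd.DataFrame(columns=["sample_id", "biotype", "condition",
                                     "libsize_factor"])
        return pd.DataFrame(index=pd.Index([], name="region")), meta, {}
    rng = cfg.rng(stream)
    biotypes = list(sample_biotypes) if sample_biotypes is not None else cfg.biotype_names()
    n_samples = len(biotypes) * cfg.n_samples_per_biotype
    if n_samples < 2:
        raise ValueError("need at least 2 samples")

    lo, hi = cfg.nb_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(regions)))
    lib = np.exp(rng.normal(0.0, cfg.libsize_lognormal_sd, size=n_samples))
    if np.any(lib <= 0):
        raise ValueError("non-positive library size factor")

    if region_biotypes is None:
        region_biotypes = {}
        n_markers = int(np.floor(cfg.marker_fraction * len(regions)))
        pool = rng.permutation(len(regions))
        k = 0
        for b in dict.fromkeys(biotypes):
            for _ in range(n_markers):
                if k >= len(pool):
                    break
                region_biotypes[regions[pool[k]]] = b
                k += 1
    marker_truth = dict(region_biotypes)

    sample_b = np.repeat(biotypes, cfg.n_samples_per_biotype)
    sample_ids = [f"{condition}_s{i:04d}.{b}" for i, b in enumerate(sample_b)]
    effect = np.ones((len(regions), n_samples))
    for r_i, region in enumerate(regions):
        b = marker_truth.get(region)
        if b is not None:
            effect[r_i, sample_b == b] = 2.0 ** cfg.effect_log2fc

    mu = base[:, None] * lib[None, :] * effect
    alpha = cfg.nb_overdispersion
    if alpha > 0:
        n_param = 1.0 / alpha
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    else:
        counts = rng.poisson(mu)
    counts = pd.DataFrame(counts, index=pd.Index(regions, name="region"),
                          columns=sample_ids)
    meta = pd.DataFrame({"sample_id": sample_ids, "biotype": sample_b,
                         "condition": condition, "libsize_factor": lib})
    return counts, meta, marker_truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def simulate_survival(samples, planted_regions, residuals: pd.DataFrame,
                      cfg: SimConfig) -> pd.DataFrame:
    """Exponential event times with hazard h0 * exp(log_hr * residual).

    The linear predictor sums ``hazard_log_hr`` times the (clipped Pearson)
    residual over the planted regions. Censoring is independent exponential,
    tuned to the configured ``censoring_rate``; ``censoring_rate=1`` censors
    everything (at the would-be event times).

    Returns a SurvivalTable DataFrame (sample_id, time, event).
    """
    planted_regions = list(planted_regions)
    missing = [r for r in planted_regions if r not in residuals.index]
    if missing:
        raise KeyError(f"planted regions absent from residuals: {missing}")
    rng = cfg.rng("survival")
    samples = list(samples)
    lp = np.zeros(len(samples))
    for r in planted_regions:
        lp += cfg.hazard_log_hr * residuals.loc[r, samples].to_numpy(dtype=float)
    rate = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if cfg.censoring_rate >= 1.0:
        time, event = t_event, np.zeros(len(samples), dtype=int)
    elif cfg.censoring_rate <= 0.0:
        time, event = t_event, np.ones(len(samples), dtype=int)
    else:
        # exponential censoring with rate c/(1-c) * mean event rate gives
        # P(censor) ~= censoring_rate for exponential event times
        c_rate = cfg.censoring_rate / (1 - cfg.censoring_rate) * np.mean(rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(samples))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    return pd.DataFrame({"sample_id": samples,
                         "time": np.maximum(time, 1e-8), "event": event})


# ---------------------------------------------------------------------------
# Per-base coverage profiles
# ---------------------------------------------------------------------------

def simulate_region_coverage(cfg: SimConfig, n_regions: int = 50,
                             n_samples: int = 5, length: int = 1000,
                             mean_depth: float = 200.0):
    """Per-base read coverage of standardized regions in two profile shapes.

    Half the regions get a narrow central Gaussian bump (sd 60 bp), half a
    plateau spanning the region, mirroring the two transcriptional patterns
    seen at 1-kb bound regions. Returns ``(coverage, shapes)`` with coverage
    shaped (n_samples, n_regions, length) and shapes a list of
    "bump"/"plateau" per region.
    """
    rng = cfg.rng("coverage")
    x = np.arange(length)
    shapes = ["bump" if i % 2 == 0 else "plateau" for i in range(n_regions)]
    cov = np.zeros((n_samples, n_regions, length))
    for r, shape in enumerate(shapes):
        if shape == "bump":
            profile = np.exp(-0.5 * ((x - length / 2) / 60.0) ** 2)
        else:
            profile = np.ones(length) * 0.5
        profile = profile / profile.sum()
        for s in range(n_samples):
            depth = rng.poisson(mean_depth * profile * length)
            cov[s, r] = depth
    return cov, shapes


# ---------------------------------------------------------------------------
# Manifest writer
# ---------------------------------------------------------------------------

def write_simulation(cfg: SimConfig, outdir) -> dict:
    """Emit all synthetic inputs under one directory with a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, peaks, truth = simulate_peak_datasets(cfg)
    transcripts, blacklist = simulate_annotation(cfg)

    manifest = {"config": asdict(cfg), "files": {}}
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for ds_id, grp in peaks.groupby("dataset_id"):
        path = peak_dir / f"{ds_id}.narrowPeak"
        write_narrowpeak(grp, path)
    manifest["files"]["peaks_dir"] = "peaks"
    datasets.to_csv(outdir / "datasets.tsv", sep="\t", index=False)
    manifest["files"]["datasets"] = "datasets.tsv"
    truth.to_csv(outdir / "locus_truth.tsv", sep="\t", index=False)
    manifest["files"]["locus_truth"] = "locus_truth.tsv"
    write_gff3_transcripts(transcripts, outdir / "transcripts.gff3")
    manifest["files"]["transcripts"] = "transcripts.gff3"
    write_bed(blacklist, outdir / "blacklist.bed")
    manifest["files"]["blacklist"] = "blacklist.bed"

    counts, meta, markers = simulate_count_matrix(
        [f"region{i}" for i in range(max(cfg.n_source_loci, 1))], cfg)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    meta.to_csv(outdir / "sample_meta.tsv", sep="\t", index=False)
    pd.Series(markers, name="biotype").rename_axis("region").to_csv(
        outdir / "marker_truth.tsv", sep="\t")
    manifest["files"].update({"counts": "counts.tsv",
                              "sample_meta": "sample_meta.tsv",
                              "marker_truth": "marker_truth.tsv"})
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
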