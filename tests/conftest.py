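import numpy as np
import pandas as pd
import pytest

from polatlas.simulate import (SimConfig, simulate_annotation,
                               simulate_count_matrix, simulate_peak_datasets)
from polatlas.genomic_io import build_intergenic_mask, filter_dataset_peaks
from polatlas.consensus import KernelConfig, build_occupancy_matrix, segment_consensus
from polatlas.transform import (detectability_rank, filter_low_counts,
                                fit_regularized_nb, pearson_residuals,
                                pooling_size_factors)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_biotypes=4, n_source_loci=80, n_datasets=16,
                     peaks_per_dataset=60, n_samples_per_biotype=15)


@pytest.fixture(scope="session")
def atlas(small_cfg):
    """Peaks -> filtered -> consensus -> occupancy, shared across tests."""
    datasets, peaks, truth = simulate_peak_datasets(small_cfg)
    transcripts, blacklist = simulate_annotation(small_cfg)
    mask = build_intergenic_mask(transcripts, blacklist)
    kept, kept_ds = filter_dataset_peaks(peaks, mask, min_peaks=10)
    consensus, membership = segment_consensus(kept, KernelConfig())
    M = build_occupancy_matrix(consensus, membership, kept, kept_ds)
    return {"datasets": datasets, "peaks": kept, "truth": truth,
            "consensus": consensus, "membership": membership, "M": M}


@pytest.fixture(scope="session")
def expression(small_cfg):
    """Counts -> size factors -> NB model -> residuals, shared across tests."""
    regions = [f"r{i:04d}" for i in range(400)]
    counts, meta, markers = simulate_count_matrix(regions, small_cfg)
    counts = filter_low_counts(counts)
    _, top = detectability_rank(counts)
    sf = pooling_size_factors(counts.loc[top])
    model = fit_regularized_nb(counts, sf, seed=0)
    residuals = pearson_residuals(counts, model)
    biotypes = meta.set_index("sample_id")["biotype"]
    return {"counts": counts, "meta": meta, "markers": markers,
            "size_factors": sf, "model": model, "residuals": residuals,
            "biotypes": biotypes}
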