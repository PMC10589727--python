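"""Consensus region calling from pooled peak summits.

Merging peak intervals directly degenerates when hundreds of experiments are
pooled (the genome becomes one merged block), so consensus elements are
instead delimited by the *local minima* of a Gaussian-smoothed density of
peak summits: every summit between two flanking minima belongs to the same
consensus, a consensus is kept when it contains peaks from at least
``min_datasets`` distinct datasets, its boundaries are those of its farthest
member peaks and its centroid is the mean member-summit position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CONSENSUS_COLUMNS = ["chrom", "start", "end", "centroid", "centroid_exact",
                     "n_peaks", "n_datasets"]


@dataclass
class KernelConfig:
    """Smoothing settings for summit-density segmentation.

    sigma : Gaussian kernel standard deviation in bp, or ``"auto"`` for
        1/8 of the average (post-filter) peak width.
    min_datasets : minimum number of distinct contributing datasets.
    """

    sigma: float | str = "auto"
    min_datasets: int = 2

    def resolve_sigma(self, peaks: pd.DataFrame) -> float:
        if self.sigma == "auto":
            widths = (peaks["end"] - peaks["start"]).to_numpy()
            if len(widths) == 0:
                raise ValueError("cannot infer sigma from an empty peak set")
            return float(widths.mean() / 8.0)
        sigma = float(self.sigma)
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        return sigma


def gaussian_kernel(sigma: float) -> np.ndarray:
    """Unit-mass Gaussian kernel on a 1-bp grid truncated at +-4 sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    radius = int(np.ceil(4 * sigma))
    x = np.arange(-radius, radius + 1)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def summit_density(summits: np.ndarray, sigma: float):
    """Smoothed per-bp summit density on ``[min - 4 sigma, max + 4 sigma]``.

    Returns ``(grid, density)`` where ``grid`` holds absolute bp positions.
    The kernel is truncated at +-4 sigma and renormalized, so the density
    integrates (sums) to the summit count.
    """
    summits = np.asarray(summits, dtype=np.int64)
    if len(summits) == 0:
        raise ValueError("need at least one summit")
    kernel = gaussian_kernel(sigma)
    radius = (len(kernel) - 1) // 2
    lo = int(summits.min()) - radius
    hi = int(summits.max()) + radius
    grid = np.arange(lo, hi + 1)
    hist = np.bincount(summits - lo, minlength=len(grid)).astype(float)
    density = np.convolve(hist, kernel, mode="same")
    return grid, density


def local_minima_cuts(density: np.ndarray) -> np.ndarray:
    """Indices of local minima of a discrete 1-d array.

    A run of equal values is a minimum when the values immediately before and
    after the run are both strictly larger; the leftmost index of the run is
    reported (deterministic plateau tie-break).
    """
    n = len(density)
    if n < 3:
        return np.array([], dtype=np.int64)
    cuts = []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and density[j + 1] == density[i]:
            j += 1
        if j < n - 1 and density[i - 1] > density[i] and density[j + 1] > density[j]:
            cuts.append(i)
        i = j + 1
    return np.asarray(cuts, dtype=np.int64)


def _round_half_even(x: float) -> int:
    return int(np.round(x))  # numpy rounds half to even


def segment_consensus(peaks: pd.DataFrame, cfg: KernelConfig | None = None):
    """Partition summits at density minima and build consensus regions.

    Parameters
    ----------
    peaks : filtered intergenic peaks (standard peak columns); may span
        multiple chromosomes.
    cfg : kernel settings; ``sigma="auto"`` uses average peak width / 8
        computed genome-wide over the input.

    Returns
    -------
    (consensus, membership) where ``consensus`` is a DataFrame with columns
    ``chrom, start, end, centroid, centroid_exact, n_peaks, n_datasets`` and
    ``membership`` maps each consensus row index to the integer-location
    indices of its member peaks in ``peaks``.
    """
    cfg = cfg or KernelConfig()
    if len(peaks) == 0:
        return pd.DataFrame(columns=CONSENSUS_COLUMNS), {}
    sigma = cfg.resolve_sigma(peaks)

    rows = []
    membership: dict[int, np.ndarray] = {}
    peaks = peaks.reset_index(drop=True)
    for chrom in sorted(peaks["chrom"].unique()):
        grp = peaks[peaks["chrom"] == chrom]
        summits = grp["summit"].to_numpy(dtype=np.int64)
        grid, density = summit_density(summits, sigma)
        cut_pos = grid[local_minima_cuts(density)]
        # segment id of each summit: summits in [cut_{m-1}, cut_m) share one
        seg = np.searchsorted(cut_pos, summits, side="right")
        for seg_id in np.unique(seg):
            members = grp.index.to_numpy()[seg == seg_id]
            sub = peaks.loc[members]
            n_datasets = sub["dataset_id"].nunique()
            if n_datasets < cfg.min_datasets:
                continue
            centroid_exact = float(sub["summit"].mean())
            rows.append({
                "chrom": chrom,
                "start": int(sub["start"].min()),
                "end": int(sub["end"].max()),
                "centroid": _round_half_even(centroid_exact),
                "centroid_exact": centroid_exact,
                "n_peaks": int(len(sub)),
                "n_datasets": int(n_datasets),
            })
            membership[len(rows) - 1] = members
    consensus = pd.DataFrame(rows, columns=CONSENSUS_COLUMNS)
    return consensus, membership


def build_occupancy_matrix(consensus: pd.DataFrame, membership: dict,
                           peaks: pd.DataFrame, dataset_ids) -> pd.DataFrame:
    """Boolean datasets x consensus membership matrix M.

    ``M[k, j]`` is True iff dataset ``k`` contributed at least one member
    peak to consensus ``j`` (multiple peaks still give a single True).
    """
    dataset_ids = list(dataset_ids)
    known = set(dataset_ids)
    M = pd.DataFrame(False, index=dataset_ids,
                     columns=consensus.index, dtype=bool)
    peaks = peaks.reset_index(drop=True)
    for j, members in membership.items():
        ds = peaks.loc[members, "dataset_id"].unique()
        unknown = set(ds) - known
        if unknown:
            raise KeyError(f"unknown dataset ids in consensus {j}: {sorted(unknown)}")
        M.loc[list(ds), j] = True
    return M


def standardize_regions(consensus: pd.DataFrame, chrom_sizes: dict[str, int],
                        width: int = 1000) -> pd.DataFrame:
    """Fixed-width windows centered on consensus centroids.

    Each region becomes ``[centroid - width/2, centroid + width/2)``; windows
    running off a chromosome end are shifted back inside (length preserved).
    A chromosome shorter than ``width`` is an error, as is an odd ``width``.
    """
    if width % 2 != 0:
        raise ValueError("width must be even")
    half = width // 2
    rows = []
    for _, row in consensus.iterrows():
        size = chrom_sizes[row["chrom"]]
        if size < width:
            raise ValueError(f"chromosome {row['chrom']} shorter than width {width}")
        start = int(row["centroid"]) - half
        start = min(max(start, 0), size - width)
        rows.append({"chrom": row["chrom"], "start": start, "end": start + width})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    out.index = consensus.index
    return out


def write_consensus_bed(consensus: pd.DataFrame, path) -> None:
    """BED6+3 export: name, score=0, strand '.', then centroid/n_peaks/n_datasets."""
    df = pd.DataFrame({
        "chrom": consensus["chrom"],
        "start": consensus["start"],
        "end": consensus["end"],
        "name": [f"consensus_{i}" for i in consensus.index],
        "score": 0,
        "strand": ".",
        "centroid": consensus["centroid"],
        "n_peaks": consensus["n_peaks"],
        "n_datasets": consensus["n_datasets"],
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def write_occupancy(M: pd.DataFrame, path) -> None:
    M.astype(int).to_csv(path, sep="\t")


def read_occupancy(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(int)
    return df.astype(bool)
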