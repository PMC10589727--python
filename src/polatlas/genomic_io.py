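"""Genomic interval containers, standard-format IO and intergenic filtering.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
Peaks are carried as a :class:`pandas.DataFrame` with columns
``chrom, start, end, summit, qvalue, dataset_id`` where ``summit`` is an
absolute base-pair position (the narrowPeak relative offset is converted on
read) and ``qvalue`` is on the -log10 scale of narrowPeak column 9.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "qvalue", "dataset_id"]


@dataclass
class DatasetInfo:
    """A ChIP-seq dataset and its normalized tissue-of-origin label."""

    dataset_id: str
    biotype: str
    n_intergenic_peaks: int = 0

    def __post_init__(self) -> None:
        if not self.biotype:
            raise ValueError("biotype must be non-empty")


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


class IntervalSet:
    """Per-chromosome sorted intervals with optional strand.

    Intervals are stored as parallel int64 arrays per chromosome, sorted by
    start. ``merge`` collapses overlapping/adjacent intervals, after which
    point and interval queries run by binary search.
    """

    def __init__(self, intervals: dict[str, np.ndarray] | None = None,
                 strands: dict[str, np.ndarray] | None = None):
        # intervals[chrom] is an (n, 2) int64 array sorted by start
        self.intervals: dict[str, np.ndarray] = {}
        self.strands: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if np.any(arr[:, 0] > arr[:, 1]):
                    raise ValueError("interval start > end")
                order = np.argsort(arr[:, 0], kind="stable")
                self.intervals[chrom] = arr[order]
                if strands and chrom in strands:
                    self.strands[chrom] = np.asarray(strands[chrom])[order]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IntervalSet":
        intervals = {}
        strands = {}
        has_strand = "strand" in df.columns
        for chrom, grp in df.groupby("chrom", sort=True):
            intervals[chrom] = grp[["start", "end"]].to_numpy(dtype=np.int64)
            if has_strand:
                strands[chrom] = grp["strand"].to_numpy()
        return cls(intervals, strands if has_strand else None)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self.intervals):
            arr = self.intervals[chrom]
            d = pd.DataFrame({"chrom": chrom, "start": arr[:, 0], "end": arr[:, 1]})
            if chrom in self.strands:
                d["strand"] = self.strands[chrom]
            rows.append(d)
        if not rows:
            return pd.DataFrame(columns=["chrom", "start", "end"])
        return pd.concat(rows, ignore_index=True)

    @property
    def chroms(self):
        return sorted(self.intervals)

    def __len__(self) -> int:
        return sum(len(a) for a in self.intervals.values())

    def total_coverage(self) -> int:
        """Total covered base pairs (intervals merged first)."""
        merged = self.merge()
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in merged.intervals.values()))

    def merge(self) -> "IntervalSet":
        """Collapse overlapping or bookended intervals. Strand is dropped."""
        out = {}
        for chrom, arr in self.intervals.items():
            if len(arr) == 0:
                continue
            starts, ends = arr[:, 0], arr[:, 1]
            keep_start = [starts[0]]
            keep_end = [ends[0]]
            for s, e in zip(starts[1:], ends[1:]):
                if s <= keep_end[-1]:
                    keep_end[-1] = max(keep_end[-1], e)
                else:
                    keep_start.append(s)
                    keep_end.append(e)
            out[chrom] = np.column_stack([keep_start, keep_end]).astype(np.int64)
        return IntervalSet(out)

    def union(self, other: "IntervalSet") -> "IntervalSet":
        out = {}
        for chrom in set(self.intervals) | set(other.intervals):
            parts = [s.intervals[chrom] for s in (self, other) if chrom in s.intervals]
            arr = np.vstack(parts)
            out[chrom] = arr[np.argsort(arr[:, 0], kind="stable")]
        return IntervalSet(out).merge()

    def pad(self, pad: int) -> "IntervalSet":
        """Extend every interval by ``pad`` bp on both sides, clipping at 0."""
        out = {}
        for chrom, arr in self.intervals.items():
            padded = arr.copy()
            padded[:, 0] = np.maximum(padded[:, 0] - pad, 0)
            padded[:, 1] = padded[:, 1] + pad
            out[chrom] = padded
        return IntervalSet(out)

    def overlaps_interval(self, chrom: str, start: np.ndarray, end: np.ndarray) -> np.ndarray:
        """Boolean: does each query ``[start, end)`` share >=1 bp with the set?

        The set is assumed merged (call ``merge()`` first for general sets).
        """
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if chrom not in self.intervals or len(self.intervals[chrom]) == 0:
            return np.zeros(start.shape, dtype=bool)
        arr = self.intervals[chrom]
        # index of first interval with set_start >= query end -> check predecessor
        idx = np.searchsorted(arr[:, 0], end, side="left") - 1
        valid = idx >= 0
        hit = np.zeros(start.shape, dtype=bool)
        hit[valid] = arr[idx[valid], 1] > start[valid]
        return hit

    def contains_points(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Boolean: is each 1-bp point inside some interval (half-open)?"""
        pos = np.asarray(pos, dtype=np.int64)
        return self.overlaps_interval(chrom, pos, pos + 1)


# ---------------------------------------------------------------------------
# Format readers / writers
# ---------------------------------------------------------------------------

def read_narrowpeak(path, dataset_id: str | None = None) -> pd.DataFrame:
    """Read an ENCODE narrowPeak (BED6+4) file into the peak DataFrame.

    Column 10 (summit offset relative to start, -1 if absent) is converted to
    an absolute position; missing summits fall back to the interval midpoint.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand",
               "signal", "pvalue", "qvalue", "peak"],
    )
    summit = np.where(df["peak"].to_numpy() >= 0,
                      df["start"].to_numpy() + df["peak"].to_numpy(),
                      (df["start"].to_numpy() + df["end"].to_numpy()) // 2)
    out = df[["chrom", "start", "end", "qvalue"]].copy()
    out["summit"] = summit.astype(np.int64)
    out["dataset_id"] = dataset_id if dataset_id is not None else df["name"]
    _validate_peaks(out)
    return out[PEAK_COLUMNS]


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    _validate_peaks(peaks)
    out = pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["start"],
        "end": peaks["end"],
        "name": peaks["dataset_id"],
        "score": 0,
        "strand": ".",
        "signal": 0.0,
        "pvalue": -1.0,
        "qvalue": peaks["qvalue"],
        "peak": peaks["summit"] - peaks["start"],
    })
    with _open(path, "wt") as fh:
        out.to_csv(fh, sep="\t", header=False, index=False)


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6 (gzip transparent) into an :class:`IntervalSet`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] >= 6:
        df = df.rename(columns={5: "strand"})
        return IntervalSet.from_dataframe(df[["chrom", "start", "end", "strand"]])
    return IntervalSet.from_dataframe(df[["chrom", "start", "end"]])


def write_bed(ivs: IntervalSet, path) -> None:
    df = ivs.to_dataframe()
    cols = ["chrom", "start", "end"]
    if "strand" in df.columns:
        df["name"] = "."
        df["score"] = 0
        cols = ["chrom", "start", "end", "name", "score", "strand"]
    with _open(path, "wt") as fh:
        df[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_gff3_transcripts(path, feature_types=("transcript", "mRNA")) -> IntervalSet:
    """Read transcript-level features from a GFF3 file.

    GFF3 is 1-based closed; coordinates are converted to 0-based half-open.
    Only the listed feature types are kept; attributes are ignored.
    """
    rows = []
    with _open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 8 or parts[2] not in feature_types:
                continue
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), parts[6]))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    return IntervalSet.from_dataframe(df)


def write_gff3_transcripts(ivs: IntervalSet, path, feature_type="transcript",
                           source="polatlas") -> None:
    df = ivs.to_dataframe()
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for i, row in df.iterrows():
            strand = row.get("strand", ".")
            fh.write(f"{row['chrom']}\t{source}\t{feature_type}\t"
                     f"{row['start'] + 1}\t{row['end']}\t.\t{strand}\t.\t"
                     f"ID=t{i}\n")


def _validate_peaks(peaks: pd.DataFrame) -> None:
    if len(peaks) == 0:
        return
    if np.any(peaks["start"].to_numpy() >= peaks["end"].to_numpy()):
        raise ValueError("peak with start >= end")
    bad = (peaks["summit"].to_numpy() < peaks["start"].to_numpy()) | (
        peaks["summit"].to_numpy() >= peaks["end"].to_numpy())
    if np.any(bad):
        raise ValueError("peak summit outside [start, end)")


# ---------------------------------------------------------------------------
# Intergenic masking and peak/dataset filters
# ---------------------------------------------------------------------------

def build_intergenic_mask(transcripts: IntervalSet, blacklist: IntervalSet,
                          pad: int = 1000) -> IntervalSet:
    """Excluded genomic space: transcripts padded by ``pad`` plus blacklist.

    Everything *outside* the returned (merged) set is intergenic.
    """
    return transcripts.pad(pad).union(blacklist)


def filter_dataset_peaks(peaks: pd.DataFrame, mask: IntervalSet,
                         q_threshold: float = 5.0, min_peaks: int = 100,
                         known_chroms=None):
    """Apply the intergenic, significance and dataset-size filters.

    Parameters
    ----------
    peaks : DataFrame with the standard peak columns.
    mask : excluded space; peaks sharing >=1 bp with it are dropped.
    q_threshold : -log10 q-value cutoff; a peak is kept when its ``qvalue``
        column (narrowPeak col 9) is strictly greater (col 9 > 5 <=> q < 1e-5).
    min_peaks : datasets with fewer surviving intergenic peaks are dropped
        entirely.
    known_chroms : optional collection of valid chromosome names; peaks on
        other chromosomes are dropped with a warning.

    Returns
    -------
    (kept_peaks, kept_dataset_ids)
    """
    peaks = peaks.copy()
    if known_chroms is not None:
        unknown = ~peaks["chrom"].isin(list(known_chroms))
        if unknown.any():
            dropped = sorted(peaks.loc[unknown, "chrom"].unique())
            warnings.warn(f"dropping {int(unknown.sum())} peaks on unknown "
                          f"chromosomes: {dropped}")
            logger.warning("dropped peaks on unknown chromosomes: %s", dropped)
            peaks = peaks[~unknown]

    keep = np.ones(len(peaks), dtype=bool)
    merged = mask.merge()
    for chrom, grp in peaks.groupby("chrom"):
        hit = merged.overlaps_interval(chrom, grp["start"].to_numpy(),
                                       grp["end"].to_numpy())
        keep[peaks.index.get_indexer(grp.index)] &= ~hit
    peaks = peaks[keep]
    peaks = peaks[peaks["qvalue"].to_numpy() > q_threshold]

    counts = peaks.groupby("dataset_id").size()
    kept_datasets = sorted(counts.index[counts >= min_peaks])
    peaks = peaks[peaks["dataset_id"].isin(kept_datasets)]
    return peaks.reset_index(drop=True), kept_datasets


def intersect_centroids(points, features: IntervalSet) -> np.ndarray:
    """True iff each (chrom, pos) 1-bp point lies inside a feature interval."""
    merged = features.merge()
    points = list(points)
    out = np.zeros(len(points), dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for i, (chrom, pos) in enumerate(points):
        by_chrom.setdefault(chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        pos = np.array([points[i][1] for i in idx], dtype=np.int64)
        out[np.array(idx)] = merged.contains_points(chrom, pos)
    return out
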