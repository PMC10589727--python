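"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's histogram/convolution code path:
the density is evaluated as an explicit kernel sum at every base pair and
minima are found by an exhaustive scan.
"""

import numpy as np


def oracle_segments(peaks, sigma, min_datasets=2):
    """Reference segmentation by explicit per-bp kernel sums.

    Returns (regions, density, grid_start) where regions is a list of dicts
    with start/end/centroid/members (sorted integer-location indices).
    """
    summits = peaks["summit"].to_numpy()
    radius = int(np.ceil(4 * sigma))
    offsets = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (offsets / sigma) ** 2)
    kernel /= kernel.sum()

    lo = int(summits.min()) - radius
    hi = int(summits.max()) + radius
    positions = np.arange(lo, hi + 1)
    # explicit kernel-sum evaluation: offset of every bp to every summit
    diff = positions[:, None] - summits[None, :]
    inside = np.abs(diff) <= radius
    density = np.where(inside, kernel[np.clip(diff + radius, 0,
                                              len(kernel) - 1)], 0.0).sum(axis=1)

    cuts = []
    i = 1
    n = len(density)
    while i < n - 1:
        j = i
        while j + 1 < n and density[j + 1] == density[i]:
            j += 1
        if (j < n - 1 and density[i - 1] > density[i]
                and density[j + 1] > density[j]):
            cuts.append(lo + i)
        i = j + 1

    regions = []
    bounds = [-np.inf] + cuts + [np.inf]
    for a, b in zip(bounds[:-1], bounds[1:]):
        members = peaks[(peaks["summit"] >= a) & (peaks["summit"] < b)]
        if len(members) == 0:
            continue
        if members["dataset_id"].nunique() < min_datasets:
            continue
        regions.append({
            "start": int(members["start"].min()),
            "end": int(members["end"].max()),
            "centroid": int(np.round(members["summit"].mean())),
            "members": sorted(members.index.tolist()),
        })
    return regions, density, lo
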