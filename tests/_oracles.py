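"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by direct enumeration rather than
calling the package implementation they check.
"""

from __future__ import annotations

import math


def bin_bedgraph_bruteforce(
    intervals: list[tuple[int, int, float]], chrom_length: int, bin_size: int
) -> list[float]:
    """Expand a bedGraph to per-base values and average each fixed bin."""
    per_base = [0.0] * chrom_length
    for start, end, value in intervals:
        for pos in range(start, end):
            per_base[pos] = value
    n_bins = math.ceil(chrom_length / bin_size)
    out = []
    for b in range(n_bins):
        chunk = per_base[b * bin_size : min((b + 1) * bin_size, chrom_length)]
        out.append(sum(chunk) / len(chunk))
    return out


def depth_segments_bruteforce(
    depths: list[float],
    bin_size: int,
    min_seg_len: int,
    outlier_cap: float,
) -> list[tuple[int, int, str]]:
    """Per-bin label + merge segmentation, enumerated directly.

    Returns (start_bin, end_bin_exclusive, label) tuples.  Bins above the
    outlier cap are excluded from the mean/SD and break runs.
    """
    retained = [d for d in depths if d <= outlier_cap]
    if not retained:
        return []
    mu = sum(retained) / len(retained)
    var = sum((d - mu) ** 2 for d in retained) / len(retained)
    sigma = math.sqrt(var)
    if sigma == 0:
        return []
    labels = []
    for d in depths:
        if d > outlier_cap:
            labels.append(None)
        elif d <= mu - sigma:
            labels.append("DEL")
        elif d >= mu + sigma:
            labels.append("DUP")
        else:
            labels.append(None)
    segments = []
    i = 0
    while i < len(labels):
        if labels[i] is None:
            i += 1
            continue
        j = i
        while j + 1 < len(labels) and labels[j + 1] == labels[i]:
            j += 1
        if (j + 1 - i) * bin_size >= min_seg_len:
            segments.append((i, j + 1, labels[i]))
        i = j + 1
    return segments


def window_counts_bruteforce(
    positions: list[int], classes: list[str], window: int, n_windows: int
) -> dict[str, list[int]]:
    """Recount SV allele classes per window from scratch (1-based positions)."""
    out = {
        "HOM_REF": [0] * n_windows,
        "HET": [0] * n_windows,
        "HOM_ALT": [0] * n_windows,
    }
    for pos, cls in zip(positions, classes):
        out[cls][(pos - 1) // window] += 1
    return out


def nearest_gene_bruteforce(
    start: int, end: int, gene_bounds: list[tuple[int, int]]
) -> int:
    """All-pairs minimum gap between [start, end) and gene intervals."""
    best = None
    for gs, ge in gene_bounds:
        if start < ge and gs < end:
            d = 0
        elif end <= gs:
            d = gs - end
        else:
            d = start - ge
        best = d if best is None else min(best, d)
    return best
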