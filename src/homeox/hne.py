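"""Non-reciprocal homoeologous exchange (NRHE) calling.

In an allopolyploid, recombination between homoeologous chromosomes of the
A and C subgenomes can delete a segment from one chromosome and duplicate
its counterpart on the homoeologous partner.  The depth signature is a
deleted segment (coverage below mean - 1 SD) on one chromosome paired with
a duplicated segment (above mean + 1 SD) on its partner, carrying the
*same* genes through a selected homoeologous gene-pair table.

Pipeline per sample: SD-threshold depth segmentation per chromosome (>= 25
kb segments, 150x outlier cap) -> match (DEL, DUP) segment pairs across
homoeologous chromosomes through selected gene pairs -> refine the
duplication extent on a coarse 100 kbp grid where coverage shows both a
1.25-fold increase over the chromosome mean and exceeds mean + 1 SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .models import CoverageTrack, GeneModel, GenomicInterval
from .rearrangements import RearrangementCall

__all__ = [
    "HneParams",
    "HomoeologPair",
    "DepthSegment",
    "NRHECall",
    "select_pairs",
    "call_depth_segments",
    "match_nrhe",
    "refine_duplication_extent",
    "classify_rearrangements",
]


@dataclass
class HneParams:
    pair_min_similarity: float = 70.0
    min_seg_len: int = 25_000
    outlier_cap: float = 150.0
    dup_bin_size: int = 100_000
    dup_outlier_cap: float = 100.0
    dup_fold: float = 1.25
    overlap_frac: float = 0.5  # gene-in-segment overlap requirement
    min_pairs: int = 1

    def __post_init__(self) -> None:
        if self.min_seg_len <= 0 or self.dup_bin_size <= 0:
            raise ConfigError("segment lengths and bin sizes must be positive")
        if not 0 < self.overlap_frac <= 1:
            raise ConfigError("overlap_frac must lie in (0, 1]")


@dataclass(frozen=True)
class HomoeologPair:
    gene_a: str
    gene_c: str
    similarity: float


@dataclass
class DepthSegment:
    sample: str
    chrom: str
    interval: GenomicInterval
    seg_type: str  # DEL | DUP
    mean_depth: float


@dataclass
class NRHECall:
    sample: str
    del_segment: DepthSegment
    dup_segment: DepthSegment
    supporting_pairs: list[HomoeologPair]
    refined_dup: GenomicInterval
    #: True once the duplication passed the coarse-grid 1.25-fold + 1 SD
    #: verification (see :func:`refine_duplication_extent`)
    dup_refined: bool = False


def select_pairs(
    candidates: pd.DataFrame, params: HneParams | None = None
) -> list[HomoeologPair]:
    """Select at most one homoeologous partner per gene.

    Rows below ``pair_min_similarity`` are dropped; the remaining rows are
    taken in order of descending similarity with ties broken by their
    position in the input (the first reported pair wins), and a row is kept
    only while both of its genes are still unpaired.
    """
    params = params or HneParams()
    df = candidates.reset_index(drop=True)
    df = df[df["similarity"] >= params.pair_min_similarity]
    order = df.index[np.lexsort((df.index, -df["similarity"].to_numpy()))]
    used: set[str] = set()
    selected = []
    for i in order:
        row = df.loc[i]
        if row["gene_a"] in used or row["gene_c"] in used:
            continue
        used.add(row["gene_a"])
        used.add(row["gene_c"])
        selected.append(
            HomoeologPair(row["gene_a"], row["gene_c"], float(row["similarity"]))
        )
    return selected


def call_depth_segments(
    track: CoverageTrack, params: HneParams | None = None
) -> list[DepthSegment]:
    """SD-threshold segmentation of one coverage track.

    Bins above ``outlier_cap`` are discarded before computing the
    chromosome mean and SD and are never labelled.  A retained bin is DEL
    when depth <= mean - SD and DUP when depth >= mean + SD; adjacent
    same-label bins merge (zero gap tolerance — an unlabelled or discarded
    bin breaks the run) and merged segments shorter than ``min_seg_len``
    are dropped.  A constant track (SD = 0) yields no segments.
    """
    params = params or HneParams()
    if track.bin_size > params.min_seg_len:
        raise ConfigError(
            f"bin size {track.bin_size} exceeds min segment length "
            f"{params.min_seg_len}"
        )
    widths = track.bin_widths()
    retained = track.depths <= params.outlier_cap
    if not retained.any():
        return []
    mu = np.average(track.depths[retained], weights=widths[retained])
    sigma = float(
        np.sqrt(
            np.average(
                (track.depths[retained] - mu) ** 2, weights=widths[retained]
            )
        )
    )
    if sigma == 0:
        return []
    labels = np.full(track.n_bins, "", dtype=object)
    labels[retained & (track.depths <= mu - sigma)] = "DEL"
    labels[retained & (track.depths >= mu + sigma)] = "DUP"

    segments = []
    i = 0
    while i < track.n_bins:
        if labels[i]:
            j = i
            while j + 1 < track.n_bins and labels[j + 1] == labels[i]:
                j += 1
            start = i * track.bin_size
            end = min((j + 1) * track.bin_size, track.chrom_length)
            if end - start >= params.min_seg_len:
                interval = GenomicInterval(track.chrom, start, end)
                segments.append(
                    DepthSegment(
                        sample=track.sample,
                        chrom=track.chrom,
                        interval=interval,
                        seg_type=str(labels[i]),
                        mean_depth=float(
                            np.average(
                                track.depths[i : j + 1], weights=widths[i : j + 1]
                            )
                        ),
                    )
                )
            i = j + 1
        else:
            i += 1
    return segments


def _gene_in_segment(
    gene: GeneModel, segment: GenomicInterval, overlap_frac: float
) -> bool:
    ov = gene.interval.overlap_length(segment)
    return ov >= overlap_frac * gene.interval.length


def match_nrhe(
    del_segments: Sequence[DepthSegment],
    dup_segments: Sequence[DepthSegment],
    pairs: Sequence[HomoeologPair],
    genes: Mapping[str, list[GeneModel]],
    partners: Mapping[str, str],
    params: HneParams | None = None,
) -> list[NRHECall]:
    """Pair deleted and duplicated segments across homoeologous chromosomes.

    For each same-sample (DEL, DUP) pair on partnered chromosomes, the
    supporting evidence is the set of selected homoeologous gene pairs with
    one gene inside the deletion and its partner inside the duplication
    (either orientation, >= ``overlap_frac`` of the gene).  Each DEL joins
    at most one DUP — the one with most supporting pairs, ties broken by
    larger gene-overlap mass and then by position — and a call is emitted
    when at least ``min_pairs`` pairs support it.  The refined duplication
    extent starts as the raw DUP interval (see
    :func:`refine_duplication_extent`).
    """
    params = params or HneParams()
    gene_by_id = {g.gene_id: g for chrom_genes in genes.values() for g in chrom_genes}
    calls = []
    for dseg in del_segments:
        partner = partners.get(dseg.chrom)
        if partner is None:
            continue
        best: tuple[int, int, DepthSegment, list[HomoeologPair]] | None = None
        for useg in dup_segments:
            if useg.sample != dseg.sample or useg.chrom != partner:
                continue
            support = []
            overlap_mass = 0
            for pair in pairs:
                ga, gc = gene_by_id.get(pair.gene_a), gene_by_id.get(pair.gene_c)
                if ga is None or gc is None:
                    continue
                for g_del, g_dup in ((ga, gc), (gc, ga)):
                    if g_del.interval.chrom != dseg.chrom:
                        continue
                    if _gene_in_segment(
                        g_del, dseg.interval, params.overlap_frac
                    ) and _gene_in_segment(g_dup, useg.interval, params.overlap_frac):
                        support.append(pair)
                        overlap_mass += g_dup.interval.overlap_length(useg.interval)
                        break
            if len(support) >= params.min_pairs:
                key = (len(support), overlap_mass)
                if best is None or key > (best[0], best[1]):
                    best = (len(support), overlap_mass, useg, support)
        if best is not None:
            calls.append(
                NRHECall(
                    sample=dseg.sample,
                    del_segment=dseg,
                    dup_segment=best[2],
                    supporting_pairs=best[3],
                    refined_dup=best[2].interval,
                )
            )
    return calls


def refine_duplication_extent(
    track: CoverageTrack,
    dup_segment: DepthSegment,
    params: HneParams | None = None,
) -> GenomicInterval:
    """Refine a duplication to the coarse-grid region of 1.25-fold increase.

    The track is re-binned to ``dup_bin_size`` (100 kbp by default); bins
    above ``dup_outlier_cap`` are discarded before computing the chromosome
    mean and SD.  The refined extent is the maximal run of bins satisfying
    *both* depth >= ``dup_fold`` x mean and depth >= mean + SD, choosing the
    run overlapping the matched duplication segment.  When no bin
    qualifies, the unrefined segment interval is returned.
    """
    params = params or HneParams()
    coarse = track.rebin(params.dup_bin_size)
    widths = coarse.bin_widths()
    retained = coarse.depths <= params.dup_outlier_cap
    if not retained.any():
        return dup_segment.interval
    mu = np.average(coarse.depths[retained], weights=widths[retained])
    sigma = float(
        np.sqrt(
            np.average((coarse.depths[retained] - mu) ** 2, weights=widths[retained])
        )
    )
    qualify = retained & (coarse.depths >= params.dup_fold * mu) & (
        coarse.depths >= mu + sigma
    )
    best, best_ov = None, 0
    i, n = 0, coarse.n_bins
    seg = dup_segment.interval
    while i < n:
        if qualify[i]:
            j = i
            while j + 1 < n and qualify[j + 1]:
                j += 1
            start = i * coarse.bin_size
            end = min((j + 1) * coarse.bin_size, coarse.chrom_length)
            ov = min(end, seg.end) - max(start, seg.start)
            if ov > best_ov:
                best, best_ov = GenomicInterval(coarse.chrom, start, end), ov
            i = j + 1
        else:
            i += 1
    return best if best is not None else dup_segment.interval


def refine_nrhe_calls(
    nrhe_calls: Sequence[NRHECall],
    tracks: Mapping[str, Mapping[str, CoverageTrack]],
    params: HneParams | None = None,
) -> None:
    """Refine every call's duplication extent in place.

    ``dup_refined`` records whether the coarse-grid verification found a
    qualifying 1.25-fold run (a fallback to the raw segment means the
    duplication could not be confirmed at that scale).
    """
    params = params or HneParams()
    for call in nrhe_calls:
        track = tracks[call.sample][call.dup_segment.chrom]
        refined = refine_duplication_extent(track, call.dup_segment, params)
        call.refined_dup = refined
        call.dup_refined = refined != call.dup_segment.interval


def classify_rearrangements(
    calls: Sequence[RearrangementCall],
    nrhe_calls: Sequence[NRHECall],
    require_refined: bool = True,
) -> list[tuple[RearrangementCall, NRHECall | None]]:
    """Link large rearrangement calls to NRHE evidence.

    A large call becomes an NRHE when a same-sample NRHE deletion segment
    overlaps it (the exchange explains the coverage loss); otherwise it
    remains a plain segmental deletion.  With ``require_refined`` (the
    default) the linked exchange must additionally carry a duplication
    confirmed by the coarse-grid 1.25-fold rule
    (:func:`refine_nrhe_calls`), which screens out noise-level depth
    segments that happen to share a gene pair with the deletion.  Small
    NRHE matches that touch no large call are ignored either way.
    """
    linked = []
    for call in calls:
        hit = None
        for nrhe in nrhe_calls:
            if require_refined and not nrhe.dup_refined:
                continue
            if (
                nrhe.sample == call.sample
                and nrhe.del_segment.interval.overlaps(call.interval)
            ):
                hit = nrhe
                break
        call.event_type = "NRHE" if hit is not None else "SEG_DEL"
        linked.append((call, hit))
    return linked
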