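"""Large segmental rearrangement detection from windowed coverage + SV alleles.

A spontaneous segmental deletion of the paternal haplotype leaves a joint
footprint in an F1: read depth drops to about half the chromosome mean and
the divergent SV loci inside the segment are homozygous reference instead of
heterozygous.  Detection therefore scans fixed windows (1 Mbp at full
scale) for runs with (a) no heterozygous divergent SV, (b) at least one
informative homozygous-reference divergent SV, and (c) mean depth at or
below ``half_factor`` times the chromosome mean, then refines the run's
boundaries on the fine-binned track to the region where smoothed depth
stays below the halving threshold.  Calls are finally situated relative to
an estimated centromere (telomeric / pericentromeric / interstitial).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError, RefinementError
from .models import AlleleClass, CohortModel, CoverageTrack, GenomicInterval
from .svfilter import DivergentCall

__all__ = [
    "DetectionParams",
    "WindowProfile",
    "RearrangementCall",
    "CentromereEstimate",
    "build_window_profiles",
    "detect_candidate_regions",
    "refine_boundaries",
    "estimate_centromere",
    "classify_location",
    "detect_rearrangements",
]


@dataclass
class DetectionParams:
    """Geometry and thresholds of the window scan.

    ``half_factor`` is 0.6 rather than a strict 0.5 because observed
    deleted-segment/chromosome coverage ratios scatter up to ~0.59; a hard
    halving cut would reject genuine events.  At the 1:4 desk scale used by
    the synthetic cohorts, pass ``window=min_event_len=250_000`` and
    ``pericen_dist=500_000``.
    """

    window: int = 1_000_000
    min_event_len: int = 1_000_000  # exclusive lower bound on refined calls
    min_informative: int = 1  # HOM_REF divergent SVs required per window
    half_factor: float = 0.6
    refine_factor: float = 0.75  # boundary threshold: midpoint of 0.5x and 1x
    outlier_cap: float = 150.0  # bins above this are ignored in chrom means
    smooth_k: int = 5  # moving-mean window (fine bins)
    persist_k: int = 3  # min qualifying-run length at each boundary
    gap_k: int | None = None  # bridgeable gap; None -> smooth_k
    telomere_frac: float = 0.10
    pericen_dist: int = 2_000_000
    refine_bin_max: int = 10_000

    def __post_init__(self) -> None:
        if self.window <= 0 or self.min_event_len <= 0:
            raise ConfigError("window and min_event_len must be positive")
        if not 0 < self.half_factor < 1:
            raise ConfigError("half_factor must lie in (0, 1)")
        if not 0 < self.refine_factor < 1:
            raise ConfigError("refine_factor must lie in (0, 1)")
        if self.smooth_k < 1 or self.persist_k < 1:
            raise ConfigError("smooth_k and persist_k must be >= 1")

    @property
    def effective_gap_k(self) -> int:
        return self.gap_k if self.gap_k is not None else self.smooth_k


@dataclass
class WindowProfile:
    """Per-window mean depth and divergent-SV allele-class counts for one
    sample on one chromosome."""

    sample: str
    chrom: str
    window: int
    chrom_length: int
    intervals: list[GenomicInterval]
    mean_depth: np.ndarray
    n_hom_ref: np.ndarray
    n_het: np.ndarray
    n_hom_alt: np.ndarray


@dataclass
class CentromereEstimate:
    chrom: str
    interval: GenomicInterval


@dataclass
class RearrangementCall:
    """A refined, per-sample segmental rearrangement call."""

    sample: str
    interval: GenomicInterval
    event_type: str  # SEG_DEL until NRHE linkage, or DUP
    segment_cov: float
    chrom_cov: float
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    location_class: str | None = None

    @property
    def coverage_ratio(self) -> float:
        return self.segment_cov / self.chrom_cov


def build_window_profiles(
    tracks: Mapping[str, CoverageTrack],
    divergent: Sequence[DivergentCall],
    window: int = 1_000_000,
) -> dict[str, dict[str, WindowProfile]]:
    """Tile each chromosome with fixed windows and combine width-weighted
    mean depth with the sample's allele-class counts among divergent SVs.

    ``tracks`` maps chromosome -> track for *one* sample when called
    directly; the convenience layering in :func:`detect_rearrangements`
    assembles profiles for all F1 samples.  Here ``tracks`` is
    ``{chrom: track}`` for the sample named by each track.
    """
    profiles: dict[str, dict[str, WindowProfile]] = {}
    for chrom, track in tracks.items():
        if window % track.bin_size:
            raise ConfigError(
                f"window {window} is not a multiple of bin size {track.bin_size}"
            )
        length = track.chrom_length
        n_win = -(-length // window)
        intervals = [
            GenomicInterval(chrom, w * window, min((w + 1) * window, length))
            for w in range(n_win)
        ]
        widths = track.bin_widths()
        per_win = window // track.bin_size
        mean_depth = np.empty(n_win)
        for w in range(n_win):
            sl = slice(w * per_win, (w + 1) * per_win)
            mean_depth[w] = np.average(track.depths[sl], weights=widths[sl])
        hom_ref = np.zeros(n_win, dtype=int)
        het = np.zeros(n_win, dtype=int)
        hom_alt = np.zeros(n_win, dtype=int)
        for call in divergent:
            rec = call.record
            if rec.chrom != chrom:
                continue
            w = (rec.pos - 1) // window
            cls = rec.calls[track.sample].allele_class
            if cls is AlleleClass.HOM_REF:
                hom_ref[w] += 1
            elif cls is AlleleClass.HET:
                het[w] += 1
            elif cls is AlleleClass.HOM_ALT:
                hom_alt[w] += 1
        profiles.setdefault(track.sample, {})[chrom] = WindowProfile(
            sample=track.sample,
            chrom=chrom,
            window=window,
            chrom_length=length,
            intervals=intervals,
            mean_depth=mean_depth,
            n_hom_ref=hom_ref,
            n_het=het,
            n_hom_alt=hom_alt,
        )
    return profiles


def detect_candidate_regions(
    profile: WindowProfile,
    chrom_mean: float,
    params: DetectionParams | None = None,
) -> list[GenomicInterval]:
    """Maximal runs of windows with no heterozygous divergent SV, at least
    ``min_informative`` homozygous-reference divergent SVs, and mean depth
    at or below ``half_factor`` x chromosome mean.

    Runs of any number of qualifying windows are returned; the final
    length requirement (``> min_event_len``) is enforced on the *refined*
    interval, since the window grid truncates events that end mid-window.
    """
    params = params or DetectionParams()
    ok = (
        (profile.n_het == 0)
        & (profile.n_hom_ref >= params.min_informative)
        & (profile.mean_depth <= params.half_factor * chrom_mean)
    )
    candidates = []
    i = 0
    n = len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            candidates.append(
                GenomicInterval(
                    profile.chrom,
                    profile.intervals[i].start,
                    profile.intervals[j].end,
                )
            )
            i = j + 1
        else:
            i += 1
    return candidates


def _qualifying_runs(
    qualify: np.ndarray, persist_k: int, gap_k: int
) -> list[tuple[int, int]]:
    """Runs of True of length >= persist_k, merged across gaps <= gap_k.
    Returned as [start, end) bin index pairs."""
    runs: list[tuple[int, int]] = []
    i, n = 0, len(qualify)
    while i < n:
        if qualify[i]:
            j = i
            while j + 1 < n and qualify[j + 1]:
                j += 1
            if j - i + 1 >= persist_k:
                runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= gap_k:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return merged


def refine_boundaries(
    track: CoverageTrack,
    candidate: GenomicInterval,
    chrom_mean: float,
    params: DetectionParams | None = None,
) -> GenomicInterval:
    """Refine a candidate to the positions at which coverage halves.

    The fine-binned track is smoothed with a centred moving mean
    (``smooth_k`` bins); bins below ``refine_factor`` x chromosome mean
    qualify.  The boundary threshold is deliberately the midpoint between
    the deleted (0.5x) and normal (1x) depth levels rather than the
    window-level ``half_factor``: with overdispersed bin depths a cut at
    0.6x sits within ~1.4 smoothed SDs of the deleted level itself and
    fragments the qualifying run, whereas the midpoint separates both
    levels by >2.5 SDs.  Qualifying runs shorter than ``persist_k`` are noise; gaps of
    at most ``gap_k`` bins (default: the smoothing window, since a single
    outlier raw bin contaminates up to ``smooth_k`` smoothed bins) are
    bridged.  The
    run overlapping the candidate most is selected and its ends are shifted
    by the expected offset of the smoothed threshold crossing at a
    half-coverage step (zero at the default midpoint threshold).  Raises :class:`RefinementError` when no qualifying run touches
    the candidate.  Idempotent: refining a refined interval returns it.
    """
    params = params or DetectionParams()
    if track.bin_size > params.refine_bin_max:
        raise ConfigError(
            f"refinement needs bins <= {params.refine_bin_max} bp, "
            f"got {track.bin_size}"
        )
    if candidate.chrom != track.chrom:
        raise ConfigError("candidate on a different chromosome")
    k = params.smooth_k
    kernel = np.ones(k)
    smoothed = np.convolve(track.depths, kernel, mode="same") / np.convolve(
        np.ones_like(track.depths), kernel, mode="same"
    )
    qualify = smoothed < params.refine_factor * chrom_mean
    runs = _qualifying_runs(qualify, params.persist_k, params.effective_gap_k)

    cand_lo = candidate.start // track.bin_size
    cand_hi = -(-candidate.end // track.bin_size)
    best, best_ov = None, 0
    for lo, hi in runs:
        ov = min(hi, cand_hi) - max(lo, cand_lo)
        if ov > best_ov:
            best, best_ov = (lo, hi), ov
    if best is None:
        raise RefinementError(
            f"{track.sample} {candidate.chrom}:{candidate.start}-{candidate.end}: "
            "no region below the halving threshold after smoothing"
        )
    lo, hi = best
    # expected offset of the smoothed threshold crossing from a 0.5x step:
    # the window qualifies once it holds 2k(1-t) deleted bins, whose centre
    # sits 2k(1-t) - (k+1)/2 bins inside the deletion
    shift = round(2 * k * (1 - params.refine_factor) - (k + 1) / 2)
    lo = max(0, lo - shift)
    hi = min(track.n_bins, hi + shift)
    return GenomicInterval(
        track.chrom,
        lo * track.bin_size,
        min(hi * track.bin_size, track.chrom_length),
    )


def estimate_centromere(
    repeat_hits: Sequence[GenomicInterval],
    breakpoints: Sequence[int],
    gap_max: int = 500_000,
) -> CentromereEstimate | None:
    """Locate the centromere from satellite-repeat hits + scaffold breakpoints.

    The densest cluster — the run of hits with inter-hit gaps below
    ``gap_max`` containing the most hits (ties: widest span, then leftmost)
    — approximates the centromere; its bounds are then refined outward to
    the nearest flanking scaffold breakpoints, falling back to the cluster
    bounds where no flanking breakpoint exists.  Returns None when the
    chromosome has no repeat hits.
    """
    if not repeat_hits:
        return None
    hits = sorted(repeat_hits, key=lambda h: (h.start, h.end))
    chrom = hits[0].chrom
    clusters: list[list[GenomicInterval]] = [[hits[0]]]
    for hit in hits[1:]:
        if hit.chrom != chrom:
            raise ConfigError("repeat hits span multiple chromosomes")
        if hit.start - clusters[-1][-1].end < gap_max:
            clusters[-1].append(hit)
        else:
            clusters.append([hit])
    best = max(
        clusters,
        key=lambda cl: (len(cl), cl[-1].end - cl[0].start, -cl[0].start),
    )
    lo, hi = best[0].start, best[-1].end
    left = [b for b in breakpoints if b <= lo]
    right = [b for b in breakpoints if b >= hi]
    start = max(left) if left else lo
    end = min(right) if right else hi
    return CentromereEstimate(chrom, GenomicInterval(chrom, start, max(end, start + 1)))


def classify_location(
    interval: GenomicInterval,
    centromere: CentromereEstimate | None,
    chrom_length: int,
    params: DetectionParams | None = None,
) -> str:
    """telomeric / pericentromeric / interstitial, telomeric winning ties."""
    params = params or DetectionParams()
    margin = params.telomere_frac * chrom_length
    if interval.start <= margin or interval.end >= chrom_length - margin:
        return "telomeric"
    if centromere is not None:
        if interval.distance_to(centromere.interval) <= params.pericen_dist:
            return "pericentromeric"
    return "interstitial"


def detect_rearrangements(
    tracks: Mapping[str, Mapping[str, CoverageTrack]],
    divergent: Sequence[DivergentCall],
    cohort: CohortModel,
    params: DetectionParams | None = None,
    centromeres: Mapping[str, CentromereEstimate] | None = None,
) -> tuple[list[RearrangementCall], list[str]]:
    """End-to-end scan over all F1 samples.

    Returns the refined calls plus a log of rejected candidates (those whose
    refinement failed or whose refined length did not exceed
    ``min_event_len``).
    """
    params = params or DetectionParams()
    calls: list[RearrangementCall] = []
    log: list[str] = []
    for sample in cohort.f1_samples:
        sample_tracks = tracks[sample]
        profiles = build_window_profiles(
            sample_tracks, divergent, window=params.window
        )[sample]
        for chrom, profile in profiles.items():
            track = sample_tracks[chrom]
            chrom_mean = track.mean_depth(cap=params.outlier_cap)
            refined_set: list[GenomicInterval] = []
            for cand in detect_candidate_regions(profile, chrom_mean, params):
                try:
                    refined = refine_boundaries(track, cand, chrom_mean, params)
                except RefinementError as exc:
                    log.append(f"rejected: {exc}")
                    continue
                refined_set.append(refined)
            # split candidates can refine into the same or overlapping
            # regions; collapse them to their union
            refined_set.sort(key=lambda iv: iv.start)
            merged_set: list[GenomicInterval] = []
            for iv in refined_set:
                if merged_set and iv.start <= merged_set[-1].end:
                    merged_set[-1] = GenomicInterval(
                        chrom, merged_set[-1].start, max(merged_set[-1].end, iv.end)
                    )
                else:
                    merged_set.append(iv)
            for refined in merged_set:
                if refined.length <= params.min_event_len:
                    log.append(
                        f"rejected: {sample} {refined.chrom}:{refined.start}-"
                        f"{refined.end} refined length {refined.length} <= "
                        f"{params.min_event_len}"
                    )
                    continue
                n_ref = n_het = n_alt = 0
                for call in divergent:
                    rec = call.record
                    if rec.chrom == chrom and refined.contains_pos(rec.pos - 1):
                        cls = rec.calls[sample].allele_class
                        if cls is AlleleClass.HOM_REF:
                            n_ref += 1
                        elif cls is AlleleClass.HET:
                            n_het += 1
                        elif cls is AlleleClass.HOM_ALT:
                            n_alt += 1
                centromere = (centromeres or {}).get(chrom)
                calls.append(
                    RearrangementCall(
                        sample=sample,
                        interval=refined,
                        event_type="SEG_DEL",
                        segment_cov=track.region_mean(refined),
                        chrom_cov=chrom_mean,
                        n_hom_ref=n_ref,
                        n_het=n_het,
                        n_hom_alt=n_alt,
                        location_class=classify_location(
                            refined, centromere, track.chrom_length, params
                        ),
                    )
                )
    return calls, log
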