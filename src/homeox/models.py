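"""Domain types and coordinate conventions.

All in-memory coordinates are 0-based half-open (``[start, end)``).  The
1-based conventions of VCF and GFF3 are converted at the format boundary
(:mod:`homeox.io`) and nowhere else, so interval arithmetic inside the
package never has to reason about inclusivity.

The types mirror the objects the pipeline passes between stages: one
structural variant with its per-sample genotype calls (:class:`SVRecord`),
binned read depth for one sample and chromosome (:class:`CoverageTrack`),
gene models, per-cytosine methylation observations, and the cohort layout of
a two-parent + F1 cross (:class:`CohortModel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np

from .errors import CohortError, ConfigError

__all__ = [
    "GenomicInterval",
    "AlleleClass",
    "GenotypeCall",
    "SVRecord",
    "CoverageTrack",
    "GeneModel",
    "MethylationSite",
    "CohortModel",
    "METHYLATION_CONTEXTS",
    "SITE_COLUMNS",
]

METHYLATION_CONTEXTS = ("CpG", "CHG", "CHH")

#: column order of the tabular (DataFrame) representation of methylation sites
SITE_COLUMNS = [
    "sample",
    "chrom",
    "pos",
    "strand",
    "context",
    "n_meth",
    "n_total",
    "frequency",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ConfigError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ConfigError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_pos(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between two intervals on the same chromosome (0 if they overlap)."""
        if self.chrom != other.chrom:
            raise ConfigError("distance between intervals on different chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end
        return self.start - other.end


class AlleleClass(Enum):
    """Genotype class of one sample at one SV locus.

    In a cross between two homozygous parents every F1 is expected to be
    ``HET`` at loci where the parents differ; any other class in an F1 is a
    candidate non-Mendelian signal.
    """

    HOM_REF = "0/0"
    HET = "0/1"
    HOM_ALT = "1/1"
    MISSING = "./."


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one SV: allele class plus ref/alt read support."""

    allele_class: AlleleClass
    ref_reads: int = 0
    alt_reads: int = 0

    def __post_init__(self) -> None:
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ConfigError("read supports must be non-negative")

    @property
    def total_reads(self) -> int:
        return self.ref_reads + self.alt_reads

    @property
    def alt_fraction(self) -> float:
        total = self.total_reads
        return self.alt_reads / total if total else float("nan")

    @property
    def called_allele_support(self) -> int:
        """Reads supporting the called allele: ALT reads for ALT-carrying
        calls (HET, HOM_ALT), REF reads for HOM_REF, 0 for MISSING."""
        if self.allele_class is AlleleClass.MISSING:
            return 0
        if self.allele_class is AlleleClass.HOM_REF:
            return self.ref_reads
        return self.alt_reads


@dataclass
class SVRecord:
    """One structural variant with per-sample genotype calls.

    ``pos`` follows the VCF convention (1-based).  ``sv_length`` is stored as
    an absolute value and may be ``None`` for an insertion whose length the
    caller could not resolve.  Records whose SVTYPE is outside {INS, DEL} are
    kept with the original type string so the filter cascade can report them
    as excluded rather than silently dropping them.
    """

    id: str
    chrom: str
    pos: int
    sv_type: str
    sv_length: int | None
    precise: bool
    calls: dict[str, GenotypeCall] = field(default_factory=dict)

    @property
    def is_indel(self) -> bool:
        return self.sv_type in ("INS", "DEL")

    def f1_classes(self, cohort: "CohortModel") -> list[AlleleClass]:
        return [self.calls[s].allele_class for s in cohort.f1_samples]


@dataclass
class CoverageTrack:
    """Binned mean read depth for one sample on one chromosome.

    ``depths[i]`` is the mean per-base depth of bin
    ``[i * bin_size, min((i + 1) * bin_size, chrom_length))``; the final bin
    may be partial, and all weighted statistics use true bin widths.
    """

    sample: str
    chrom: str
    bin_size: int
    chrom_length: int
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        expected = math.ceil(self.chrom_length / self.bin_size)
        if len(self.depths) != expected:
            raise ConfigError(
                f"{self.chrom}: {len(self.depths)} bins given, expected "
                f"{expected} for length {self.chrom_length} at bin {self.bin_size}"
            )
        if np.any(self.depths < 0):
            raise ConfigError("negative depth")

    @property
    def n_bins(self) -> int:
        return len(self.depths)

    def bin_widths(self) -> np.ndarray:
        widths = np.full(self.n_bins, self.bin_size, dtype=float)
        widths[-1] = self.chrom_length - (self.n_bins - 1) * self.bin_size
        return widths

    def bin_interval(self, i: int) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            i * self.bin_size,
            min((i + 1) * self.bin_size, self.chrom_length),
        )

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=int) * self.bin_size

    def mean_depth(self, cap: float | None = None) -> float:
        """Width-weighted mean depth, optionally ignoring bins above ``cap``."""
        widths = self.bin_widths()
        keep = np.ones(self.n_bins, dtype=bool)
        if cap is not None:
            keep = self.depths <= cap
        if not keep.any():
            return float("nan")
        return float(np.average(self.depths[keep], weights=widths[keep]))

    def region_mean(self, interval: GenomicInterval) -> float:
        """Width-weighted mean depth over the part of the track inside ``interval``."""
        if interval.chrom != self.chrom:
            raise ConfigError("interval on a different chromosome")
        starts = self.bin_starts().astype(float)
        ends = np.minimum(starts + self.bin_size, self.chrom_length)
        ov = np.minimum(ends, interval.end) - np.maximum(starts, interval.start)
        ov = np.clip(ov, 0, None)
        if ov.sum() == 0:
            return float("nan")
        return float(np.average(self.depths, weights=ov))

    def rebin(self, new_bin_size: int) -> "CoverageTrack":
        """Aggregate to a coarser grid; ``new_bin_size`` must be a multiple
        of the current bin size.  Values are width-weighted means."""
        if new_bin_size % self.bin_size:
            raise ConfigError(
                f"new bin size {new_bin_size} is not a multiple of {self.bin_size}"
            )
        factor = new_bin_size // self.bin_size
        widths = self.bin_widths()
        n_new = math.ceil(self.chrom_length / new_bin_size)
        new_depths = np.empty(n_new)
        for j in range(n_new):
            sl = slice(j * factor, (j + 1) * factor)
            new_depths[j] = np.average(self.depths[sl], weights=widths[sl])
        return CoverageTrack(
            self.sample, self.chrom, new_bin_size, self.chrom_length, new_depths
        )


@dataclass
class GeneModel:
    """A gene with its exon structure (exons sorted, non-overlapping)."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for exon in self.exons:
            if exon.start < self.interval.start or exon.end > self.interval.end:
                raise ConfigError(f"{self.gene_id}: exon outside gene body")
            if prev_end is not None and exon.start < prev_end:
                raise ConfigError(f"{self.gene_id}: overlapping exons")
            prev_end = exon.end

    def promoter(self, chrom_length: int, width: int = 1000) -> GenomicInterval | None:
        """Strand-aware upstream promoter window, clipped to the chromosome."""
        if self.strand == "+":
            start, end = self.interval.start - width, self.interval.start
        else:
            start, end = self.interval.end, self.interval.end + width
        start, end = max(0, start), min(chrom_length, end)
        if start >= end:
            return None
        return GenomicInterval(self.interval.chrom, start, end)


@dataclass(frozen=True)
class MethylationSite:
    """Per-cytosine methylation evidence for one sample (0-based position)."""

    sample: str
    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_meth <= self.n_total):
            raise ConfigError("require 0 <= n_meth <= n_total")
        if self.context not in METHYLATION_CONTEXTS:
            raise ConfigError(f"unknown methylation context {self.context!r}")

    @property
    def frequency(self) -> float:
        return self.n_meth / self.n_total if self.n_total else 0.0


@dataclass
class CohortModel:
    """Layout of the cross: two homozygous parents and their F1 offspring."""

    maternal: str
    paternal: str
    f1_samples: list[str]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if not self.f1_samples:
            raise CohortError("cohort needs at least one F1 sample")
        parents = {self.maternal, self.paternal}
        if len(parents) != 2:
            raise CohortError("maternal and paternal samples must differ")
        if parents & set(self.f1_samples):
            raise CohortError("F1 sample ids must be disjoint from the parents")
        if len(set(self.f1_samples)) != len(self.f1_samples):
            raise CohortError("duplicate F1 sample id")

    @property
    def samples(self) -> list[str]:
        return [self.maternal, self.paternal, *self.f1_samples]

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def validate_samples(self, observed: Iterable[str]) -> None:
        observed = set(observed)
        expected = set(self.samples)
        if observed != expected:
            missing = sorted(expected - observed)
            extra = sorted(observed - expected)
            raise CohortError(
                f"sample set mismatch: missing {missing}, unexpected {extra}"
            )
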