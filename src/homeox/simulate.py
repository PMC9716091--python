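"""Synthetic allopolyploid F1 cohort generator.

Emulates, at desk scale, the data structure of a long-read resequencing
study of a two-parent cross with twelve F1 sister plants: per-sample binned
read-depth tracks, a merged multi-sample SV VCF with per-sample genotypes
and DR/DV read support, colinear homoeologous gene pairs between the A and
C subgenomes, centromeric satellite arrays with flanking scaffold
breakpoints, and per-cytosine methylation tables in the CpG/CHG/CHH
contexts.

The genetic model is deliberately simple and fully parameterised:

* the maternal parent is homozygous reference and the paternal parent
  homozygous alternate at every SV locus, so every F1 is expected to be
  uniformly heterozygous (Mendel's law of uniformity);
* a planted segmental deletion removes the paternal haplotype of its
  carrier over an interval: depth drops to 0.5x and the carrier's SV calls
  inside the interval become homozygous reference;
* a planted non-reciprocal homoeologous exchange (NRHE) couples such a
  deletion with a 1.5x duplication at the colinear position on the
  homoeologous partner chromosome;
* bin depths are negative binomial (long-read depth is overdispersed; the
  default dispersion gives variance ~ 2 x mean, which makes SD-threshold
  segmentation non-trivial);
* per-cytosine methylation has a latent per-locus level drawn from a Beta
  distribution around the context mean and *shared across samples* — the
  level is a property of the locus — with binomial read sampling per
  sample, so two samples differ only by sampling noise unless a DMR is
  planted.

All outputs are pure functions of (config, events, seed).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, EventConflictError
from .models import (
    SITE_COLUMNS,
    AlleleClass,
    CohortModel,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    GenotypeCall,
    METHYLATION_CONTEXTS,
    SVRecord,
)
from . import reference

__all__ = [
    "EventSpec",
    "DmrSpec",
    "SimConfig",
    "GenomeModel",
    "build_genome_model",
    "simulate_cohort",
    "simulate_methylome",
    "build_filter_audit_records",
    "export_cohort",
]


@dataclass(frozen=True)
class EventSpec:
    """One planted rearrangement: a segmental deletion, optionally coupled
    with a duplication on the homoeologous partner chromosome (NRHE)."""

    event_type: str  # "SEG_DEL" or "NRHE"
    carrier: str
    del_interval: GenomicInterval
    dup_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.event_type not in ("SEG_DEL", "NRHE"):
            raise ConfigError(f"unknown event type {self.event_type!r}")
        if self.event_type == "NRHE" and self.dup_interval is None:
            raise ConfigError("NRHE events require a dup_interval")
        if self.event_type == "SEG_DEL" and self.dup_interval is not None:
            raise ConfigError("SEG_DEL events must not carry a dup_interval")


@dataclass(frozen=True)
class DmrSpec:
    """A planted differential-methylation region: the carrier's latent level
    is shifted by ``delta`` (negative = hypomethylated) inside ``interval``."""

    carrier: str
    interval: GenomicInterval
    context: str
    delta: float


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the emulated study: ~40x mean long-read depth,
    overdispersed (variance ~ 2 x mean) bin depths, 97% allele purity for
    homozygous calls, balanced heterozygotes, 10 kb coverage bins, and
    CpG >= CHG >= CHH mean methylation levels with CHH sites most numerous.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=reference.scaled_chrom_lengths
    )
    depth_mean: float = 40.0
    nb_dispersion: float | None = None  # None: size = mean, i.e. var = 2 x mean
    n_sv_loci: int = 3000
    sv_alt_fraction_target: float = 0.97
    het_fraction_target: float = 0.5
    bin_size: int = 10_000
    gene_spacing: int = 20_000
    gene_length: int = 2_000
    pair_similarity_range: tuple[float, float] = (60.0, 100.0)
    meth_level_by_context: dict[str, float] = field(
        default_factory=lambda: {"CpG": 0.6, "CHG": 0.35, "CHH": 0.10}
    )
    meth_sites_per_kb: dict[str, float] = field(
        default_factory=lambda: {"CpG": 3.0, "CHG": 2.0, "CHH": 6.0}
    )
    meth_beta_concentration: float = 20.0
    meth_depth_mean: float | None = None  # None: same as depth_mean
    centromere_fraction: dict[str, float] = field(
        default_factory=lambda: dict(reference.CENTROMERE_FRACTION)
    )
    centromere_halfwidth: int = 100_000
    breakpoint_offset: int = 50_000
    chrom_copy_factor: dict[str, dict[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        for name, value in [
            ("sv_alt_fraction_target", self.sv_alt_fraction_target),
            ("het_fraction_target", self.het_fraction_target),
            *[(f"meth level {k}", v) for k, v in self.meth_level_by_context.items()],
        ]:
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if self.meth_beta_concentration <= 0:
            raise ConfigError("meth_beta_concentration must be positive")


@dataclass
class GenomeModel:
    """Static genome layout shared by all samples of one simulation."""

    cohort: CohortModel
    genes: dict[str, list[GeneModel]]
    pairs: pd.DataFrame  # columns gene_a, gene_c, similarity
    repeats: dict[str, list[GenomicInterval]]
    breakpoints: dict[str, list[int]]
    partners: dict[str, str]
    centromere_truth: dict[str, GenomicInterval]

    @property
    def all_genes(self) -> list[GeneModel]:
        return [g for genes in self.genes.values() for g in genes]

    def subgenome(self, chrom: str) -> str:
        return chrom[0]


def _rng(config: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float | None
) -> np.ndarray:
    """Negative binomial with mean ``mean``; size parameter ``dispersion`` or,
    when None, size = mean (variance = 2 x mean)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=int)
    pos = mean > 0
    if pos.any():
        m = mean[pos]
        k = np.full_like(m, dispersion) if dispersion is not None else m
        p = k / (k + m)
        out[pos] = rng.negative_binomial(k, p)
    return out


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

def build_genome_model(config: SimConfig) -> GenomeModel:
    """Lay out the cohort, colinear homoeologous genes, centromeric repeat
    arrays and scaffold breakpoints. Deterministic given ``config.seed``."""
    lengths = config.chrom_lengths
    a_chroms = sorted(c for c in lengths if c.startswith("A"))
    c_chroms = sorted(c for c in lengths if c.startswith("C"))
    if not a_chroms or not c_chroms:
        raise ConfigError("need at least one A and one C chromosome")
    partners = {
        c: p for c, p in reference.HOMOEOLOG_PARTNERS.items() if c in lengths
    }
    cohort = CohortModel(
        maternal="Express617",
        paternal="G3D001",
        f1_samples=[f"F1_{i:02d}" for i in range(1, 13)],
        chrom_lengths=dict(lengths),
    )

    rng = _rng(config, 1)
    genes: dict[str, list[GeneModel]] = {c: [] for c in lengths}
    pair_rows = []
    for a in a_chroms:
        c = partners.get(a)
        if c is None:
            continue
        n = min(lengths[a], lengths[c]) // config.gene_spacing
        if n < 1 or config.gene_length * n > min(lengths[a], lengths[c]):
            raise ConfigError(
                f"chromosome pair {a}/{c} too short for {n} genes of "
                f"{config.gene_length} bp"
            )
        sims = rng.uniform(*config.pair_similarity_range, size=n)
        for i in range(n):
            ids = {}
            for chrom in (a, c):
                center = int((i + 0.5) / n * lengths[chrom])
                half = config.gene_length // 2
                start = max(0, center - half)
                end = min(lengths[chrom], start + config.gene_length)
                strand = "+" if i % 2 == 0 else "-"
                exon_len = max(1, config.gene_length // 3)
                gene_id = f"{chrom}G{i:04d}"
                genes[chrom].append(
                    GeneModel(
                        gene_id=gene_id,
                        interval=GenomicInterval(chrom, start, end),
                        strand=strand,
                        exons=[
                            GenomicInterval(chrom, start, start + exon_len),
                            GenomicInterval(chrom, end - exon_len, end),
                        ],
                    )
                )
                ids[chrom] = gene_id
            pair_rows.append((ids[a], ids[c], float(sims[i])))
    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_c", "similarity"])

    repeats: dict[str, list[GenomicInterval]] = {}
    breakpoints: dict[str, list[int]] = {}
    centromere_truth: dict[str, GenomicInterval] = {}
    for chrom, length in lengths.items():
        center = int(config.centromere_fraction.get(chrom, 0.4) * length)
        arr_start = max(0, center - config.centromere_halfwidth)
        arr_end = min(length, center + config.centromere_halfwidth)
        hits = []
        # dense satellite array: 25 hits of 500 bp, ~8 kb apart
        step = max(1000, (arr_end - arr_start) // 25)
        for pos in range(arr_start, arr_end - 500, step):
            hits.append(GenomicInterval(chrom, pos, pos + 500))
        # scattered off-centromere satellite copies (singletons)
        for frac in (0.05, 0.20, 0.60, 0.90):
            pos = int(frac * length)
            if abs(pos - center) > 0.12 * length and pos + 500 < length:
                hits.append(GenomicInterval(chrom, pos, pos + 500))
        repeats[chrom] = sorted(hits, key=lambda h: h.start)
        bp = sorted(
            {
                max(0, arr_start - config.breakpoint_offset),
                min(length, arr_end + config.breakpoint_offset),
                int(0.10 * length),
                int(0.85 * length),
            }
        )
        breakpoints[chrom] = bp
        centromere_truth[chrom] = GenomicInterval(chrom, arr_start, arr_end)

    return GenomeModel(
        cohort=cohort,
        genes=genes,
        pairs=pairs,
        repeats=repeats,
        breakpoints=breakpoints,
        partners=partners,
        centromere_truth=centromere_truth,
    )


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

def _validate_events(
    events: Sequence[EventSpec], cohort: CohortModel
) -> None:
    for ev in events:
        if ev.carrier not in cohort.samples:
            raise ConfigError(f"event carrier {ev.carrier!r} not in cohort")
        for iv in filter(None, (ev.del_interval, ev.dup_interval)):
            if iv.chrom not in cohort.chrom_lengths:
                raise ConfigError(f"event chromosome {iv.chrom!r} unknown")
            if iv.end > cohort.chrom_lengths[iv.chrom]:
                raise ConfigError(f"event interval {iv} beyond chromosome end")
    by_carrier: dict[tuple[str, str], list[GenomicInterval]] = {}
    for ev in events:
        for iv in filter(None, (ev.del_interval, ev.dup_interval)):
            key = (ev.carrier, iv.chrom)
            for other in by_carrier.get(key, []):
                if iv.overlaps(other):
                    raise EventConflictError(
                        f"overlapping events for {ev.carrier} on {iv.chrom}: "
                        f"{iv} vs {other}"
                    )
            by_carrier.setdefault(key, []).append(iv)


def _carrier_intervals(
    events: Sequence[EventSpec], which: str
) -> dict[tuple[str, str], list[GenomicInterval]]:
    """(sample, chrom) -> planted del or dup intervals."""
    out: dict[tuple[str, str], list[GenomicInterval]] = {}
    for ev in events:
        iv = ev.del_interval if which == "del" else ev.dup_interval
        if iv is not None:
            out.setdefault((ev.carrier, iv.chrom), []).append(iv)
    return out


def _copy_factor_bins(
    n_bins: int,
    bin_size: int,
    chrom_length: int,
    dels: Sequence[GenomicInterval],
    dups: Sequence[GenomicInterval],
    whole_chrom: float = 1.0,
) -> np.ndarray:
    """Per-bin copy factor; partial bin overlap scales proportionally."""
    factor = np.full(n_bins, whole_chrom)
    starts = np.arange(n_bins, dtype=float) * bin_size
    ends = np.minimum(starts + bin_size, chrom_length)
    widths = ends - starts
    for iv, delta in [(iv, -0.5) for iv in dels] + [(iv, +0.5) for iv in dups]:
        ov = np.clip(
            np.minimum(ends, iv.end) - np.maximum(starts, iv.start), 0, None
        )
        factor += delta * ov / widths
    return factor


# ---------------------------------------------------------------------------
# cohort simulation: coverage + SVs
# ---------------------------------------------------------------------------

def simulate_cohort(
    model: GenomeModel,
    events: Sequence[EventSpec],
    config: SimConfig,
) -> tuple[dict[str, dict[str, CoverageTrack]], list[SVRecord], dict]:
    """Draw coverage tracks and the merged SV genotype matrix.

    Returns ``(tracks, records, truth)`` where ``tracks[sample][chrom]`` is a
    :class:`CoverageTrack`, ``records`` the multi-sample SV list, and
    ``truth`` a JSON-serialisable record of the planted signal (events and
    the SV loci each deletion covers).
    """
    cohort = model.cohort
    _validate_events(events, cohort)
    dels = _carrier_intervals(events, "del")
    dups = _carrier_intervals(events, "dup")

    rng_cov = _rng(config, 2)
    tracks: dict[str, dict[str, CoverageTrack]] = {}
    for sample in cohort.samples:
        tracks[sample] = {}
        for chrom, length in cohort.chrom_lengths.items():
            n_bins = math.ceil(length / config.bin_size)
            factor = _copy_factor_bins(
                n_bins,
                config.bin_size,
                length,
                dels.get((sample, chrom), []),
                dups.get((sample, chrom), []),
                whole_chrom=config.chrom_copy_factor.get(sample, {}).get(chrom, 1.0),
            )
            depths = _nb_draw(
                rng_cov, config.depth_mean * factor, config.nb_dispersion
            ).astype(float)
            tracks[sample][chrom] = CoverageTrack(
                sample, chrom, config.bin_size, length, depths
            )

    # SV loci on a jittered grid, count proportional to chromosome length
    rng_sv = _rng(config, 3)
    total_len = sum(cohort.chrom_lengths.values())
    records: list[SVRecord] = []
    truth_loci: dict[str, list[str]] = {
        f"event_{i}": [] for i in range(len(events))
    }
    for chrom, length in cohort.chrom_lengths.items():
        n_loci = max(1, round(config.n_sv_loci * length / total_len))
        spacing = length / n_loci
        jitter = rng_sv.uniform(-0.2, 0.2, size=n_loci)
        positions = np.clip(
            ((np.arange(n_loci) + 0.5 + jitter) * spacing).astype(int), 1, length
        )
        sv_types = rng_sv.choice(["INS", "DEL"], size=n_loci, p=[0.55, 0.45])
        sv_lengths = rng_sv.integers(50, 5000, size=n_loci)
        pos0 = positions - 1  # 0-based for interval membership

        # vectorised per-sample class/copy-factor/read-support arrays
        sample_calls: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for sample in cohort.samples:
            in_del = np.zeros(n_loci, dtype=bool)
            for iv in dels.get((sample, chrom), []):
                in_del |= (pos0 >= iv.start) & (pos0 < iv.end)
            in_dup = np.zeros(n_loci, dtype=bool)
            for iv in dups.get((sample, chrom), []):
                in_dup |= (pos0 >= iv.start) & (pos0 < iv.end)
            if sample == cohort.maternal:
                classes = np.full(n_loci, AlleleClass.HOM_REF, dtype=object)
            elif sample == cohort.paternal:
                classes = np.full(n_loci, AlleleClass.HOM_ALT, dtype=object)
            else:
                classes = np.full(n_loci, AlleleClass.HET, dtype=object)
                classes[in_del] = AlleleClass.HOM_REF
            factor = np.ones(n_loci)
            factor[in_del] = 0.5
            factor[in_dup] = 1.5
            p_alt = np.full(n_loci, config.het_fraction_target)
            p_alt[in_dup] = 1.0 / 3.0  # one extra maternal-like copy
            p_alt[classes == AlleleClass.HOM_ALT] = config.sv_alt_fraction_target
            p_alt[classes == AlleleClass.HOM_REF] = 1.0 - config.sv_alt_fraction_target
            n_total = np.maximum(
                1, _nb_draw(rng_sv, config.depth_mean * factor, config.nb_dispersion)
            )
            alt = rng_sv.binomial(n_total, p_alt)
            sample_calls[sample] = (classes, n_total, alt)

        for i in range(n_loci):
            calls = {
                sample: GenotypeCall(
                    cls[i], int(n_tot[i] - alt[i]), int(alt[i])
                )
                for sample, (cls, n_tot, alt) in sample_calls.items()
            }
            rec = SVRecord(
                id=f"sv_{chrom}_{i:05d}",
                chrom=chrom,
                pos=int(positions[i]),
                sv_type=str(sv_types[i]),
                sv_length=int(sv_lengths[i]),
                precise=True,
                calls=calls,
            )
            records.append(rec)
            for j, ev in enumerate(events):
                if ev.del_interval.chrom == chrom and ev.del_interval.contains_pos(
                    int(positions[i]) - 1
                ):
                    truth_loci[f"event_{j}"].append(rec.id)

    truth = {
        "events": [
            {
                "event_type": ev.event_type,
                "carrier": ev.carrier,
                "del": [ev.del_interval.chrom, ev.del_interval.start, ev.del_interval.end],
                "dup": (
                    [ev.dup_interval.chrom, ev.dup_interval.start, ev.dup_interval.end]
                    if ev.dup_interval
                    else None
                ),
            }
            for ev in events
        ],
        "loci_by_event": truth_loci,
        "n_sv_loci": len(records),
        "centromeres": {
            chrom: [iv.start, iv.end] for chrom, iv in model.centromere_truth.items()
        },
    }
    return tracks, records, truth


# ---------------------------------------------------------------------------
# methylome simulation
# ---------------------------------------------------------------------------

def simulate_methylome(
    model: GenomeModel,
    events: Sequence[EventSpec],
    config: SimConfig,
    chroms: Sequence[str] | None = None,
    samples: Sequence[str] | None = None,
    dmr_regions: Sequence[DmrSpec] = (),
) -> pd.DataFrame:
    """Per-cytosine methylation tables for the requested samples/chromosomes.

    Site positions and latent per-site levels are shared across samples;
    read totals scale with the local copy factor (halved in a carrier's
    deleted segment), so methylated-cytosine *counts* drop in deletions
    while methylation *levels* stay depth-invariant.  Planted
    :class:`DmrSpec` regions shift the carrier's latent level.
    """
    cohort = model.cohort
    _validate_events(events, cohort)
    chroms = list(chroms) if chroms is not None else list(cohort.chrom_lengths)
    samples = list(samples) if samples is not None else cohort.samples
    for sample in samples:
        if sample not in cohort.samples:
            raise ConfigError(f"unknown sample {sample!r}")
    depth = config.meth_depth_mean or config.depth_mean
    dels = _carrier_intervals(events, "del")
    dups = _carrier_intervals(events, "dup")

    rng = _rng(config, 4)
    frames = []
    for chrom in chroms:
        length = cohort.chrom_lengths[chrom]
        for context in METHYLATION_CONTEXTS:
            n_sites = int(config.meth_sites_per_kb[context] * length / 1000)
            if n_sites == 0:
                continue
            positions = np.unique(rng.integers(0, length, size=n_sites))
            strands = rng.choice(["+", "-"], size=len(positions))
            mu = config.meth_level_by_context[context]
            c = config.meth_beta_concentration
            latent = rng.beta(max(mu * c, 1e-9), max((1 - mu) * c, 1e-9),
                              size=len(positions))
            for sample in samples:
                level = latent.copy()
                for spec in dmr_regions:
                    if (
                        spec.carrier == sample
                        and spec.context == context
                        and spec.interval.chrom == chrom
                    ):
                        inside = (positions >= spec.interval.start) & (
                            positions < spec.interval.end
                        )
                        level[inside] = np.clip(level[inside] + spec.delta, 0.0, 1.0)
                factor = np.ones(len(positions))
                for iv in dels.get((sample, chrom), []):
                    factor[(positions >= iv.start) & (positions < iv.end)] = 0.5
                for iv in dups.get((sample, chrom), []):
                    factor[(positions >= iv.start) & (positions < iv.end)] = 1.5
                n_total = _nb_draw(rng, depth * factor, config.nb_dispersion)
                covered = n_total > 0
                n_meth = np.zeros(len(positions), dtype=int)
                n_meth[covered] = rng.binomial(n_total[covered], level[covered])
                frames.append(
                    pd.DataFrame(
                        {
                            "sample": sample,
                            "chrom": chrom,
                            "pos": positions[covered],
                            "strand": strands[covered],
                            "context": context,
                            "n_meth": n_meth[covered],
                            "n_total": n_total[covered],
                            "frequency": n_meth[covered] / n_total[covered],
                        }
                    )
                )
    if not frames:
        return pd.DataFrame(columns=SITE_COLUMNS)
    return pd.concat(frames, ignore_index=True)[SITE_COLUMNS]


# ---------------------------------------------------------------------------
# filter-audit fixture
# ---------------------------------------------------------------------------

def build_filter_audit_records(
    cohort: CohortModel,
) -> tuple[list[SVRecord], dict[str, str]]:
    """A deterministic 20-record set exercising the SV filter cascade.

    Eleven records are clean and must survive every stage; nine each violate
    exactly one stage.  Returns ``(records, expected_exclusion)`` where the
    mapping gives the stage name at which each doomed record must fall.
    Two of the clean records additionally carry a divergent F1 genotype
    (one sibling homozygous reference), for exercising the non-Mendelian
    selector downstream of the cascade.
    """
    hom_alt = GenotypeCall(AlleleClass.HOM_ALT, 1, 29)
    hom_ref = GenotypeCall(AlleleClass.HOM_REF, 29, 1)
    het = GenotypeCall(AlleleClass.HET, 15, 15)

    def clean_calls() -> dict[str, GenotypeCall]:
        calls = {cohort.maternal: hom_ref, cohort.paternal: hom_alt}
        calls.update({s: het for s in cohort.f1_samples})
        return calls

    chroms = list(cohort.chrom_lengths)
    records: list[SVRecord] = []
    expected: dict[str, str] = {}

    def add(rec: SVRecord, stage: str | None = None) -> None:
        records.append(rec)
        if stage is not None:
            expected[rec.id] = stage

    for i in range(11):
        calls = clean_calls()
        if i >= 9:  # two survivors with a non-Mendelian F1 pattern
            calls[cohort.f1_samples[0]] = hom_ref
        add(
            SVRecord(
                id=f"clean_{i:02d}",
                chrom=chroms[i % len(chroms)],
                pos=1000 + 1000 * i,
                sv_type="DEL" if i % 2 else "INS",
                sv_length=500 + i,
                precise=True,
                calls=calls,
            )
        )

    add(
        SVRecord("viol_type", chroms[0], 20_000, "INV", 500, True, clean_calls()),
        "sv_type",
    )
    add(
        SVRecord("viol_minlen", chroms[0], 21_000, "DEL", 30, True, clean_calls()),
        "min_length",
    )
    low = {
        cohort.maternal: GenotypeCall(AlleleClass.HOM_REF, 20, 1),
        cohort.paternal: GenotypeCall(AlleleClass.HOM_ALT, 1, 20),
    }
    low.update({s: GenotypeCall(AlleleClass.HET, 10, 10) for s in cohort.f1_samples})
    add(
        SVRecord("viol_support", chroms[0], 22_000, "DEL", 500, True, low),
        "min_support",
    )
    add(
        SVRecord("viol_precise", chroms[0], 23_000, "DEL", 500, False, clean_calls()),
        "precise",
    )
    add(
        SVRecord("viol_unresolved", chroms[0], 24_000, "INS", None, True, clean_calls()),
        "resolved_length",
    )
    paternal_het = clean_calls()
    paternal_het[cohort.paternal] = het
    add(
        SVRecord("viol_paternal", chroms[0], 25_000, "DEL", 500, True, paternal_het),
        "paternal_hom_alt",
    )
    add(
        SVRecord("viol_maxlen", chroms[0], 26_000, "DEL", 50_000, True, clean_calls()),
        "max_length",
    )
    missing = clean_calls()
    missing[cohort.f1_samples[1]] = GenotypeCall(AlleleClass.MISSING, 0, 0)
    add(
        SVRecord("viol_missing", chroms[0], 27_000, "DEL", 500, True, missing),
        "no_missing",
    )
    impure = clean_calls()
    impure[cohort.paternal] = GenotypeCall(AlleleClass.HOM_ALT, 4, 26)  # 0.867 < 0.9
    add(
        SVRecord("viol_fraction", chroms[0], 28_000, "DEL", 500, True, impure),
        "allele_support",
    )
    return records, expected


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_cohort(
    outdir: str | os.PathLike,
    model: GenomeModel,
    tracks: Mapping[str, Mapping[str, CoverageTrack]],
    records: Sequence[SVRecord],
    truth: dict,
    methylome: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write every simulated artefact as plain text; returns path map."""
    from . import io as hio

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    vcf = os.path.join(outdir, "cohort_sv.vcf")
    hio.write_sv_vcf(records, model.cohort, vcf)
    paths["sv_vcf"] = vcf

    covdir = os.path.join(outdir, "coverage")
    os.makedirs(covdir, exist_ok=True)
    for sample, by_chrom in tracks.items():
        p = os.path.join(covdir, f"{sample}.bedgraph")
        hio.write_bedgraph(by_chrom, p)
        paths[f"coverage:{sample}"] = p

    gff = os.path.join(outdir, "genes.gff3")
    hio.write_gff3(model.all_genes, gff)
    paths["genes_gff3"] = gff

    pairs = os.path.join(outdir, "homoeolog_pairs.tsv")
    model.pairs.to_csv(pairs, sep="\t", index=False)
    paths["pairs_tsv"] = pairs

    repeats = os.path.join(outdir, "centromere_repeats.bed")
    hio.write_bed(
        [iv for ivs in model.repeats.values() for iv in ivs], repeats
    )
    paths["repeats_bed"] = repeats

    bps = os.path.join(outdir, "scaffold_breakpoints.tsv")
    hio.write_breakpoints(model.breakpoints, bps)
    paths["breakpoints_tsv"] = bps

    if methylome is not None:
        methdir = os.path.join(outdir, "methylation")
        os.makedirs(methdir, exist_ok=True)
        for sample, sub in methylome.groupby("sample", sort=True):
            p = os.path.join(methdir, f"{sample}.tsv")
            hio.write_methylation_tsv(sub, p)
            paths[f"methylation:{sample}"] = p

    truth_path = os.path.join(outdir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump(truth, fh, indent=2)
    paths["truth_json"] = truth_path
    return paths
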