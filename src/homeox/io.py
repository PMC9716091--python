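"""Readers and writers for the standard formats the pipeline touches.

VCF is handled through :mod:`pysam` (4.2 dialect, sniffles-style DR/DV
read-support FORMAT fields), GFF3 through :mod:`gffutils`, and the simple
tabular formats (bedGraph, BED, methylation TSV, breakpoint lists) through
:mod:`pandas`.  Every reader converts to the package's internal 0-based
half-open convention; every writer converts back, and ``write(read(x))`` is
the identity on payload fields.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam

from .errors import CoordinateError, FormatError
from .models import (
    SITE_COLUMNS,
    AlleleClass,
    CohortModel,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    GenotypeCall,
    MethylationSite,
    SVRecord,
)

__all__ = [
    "read_sv_vcf",
    "write_sv_vcf",
    "read_bedgraph",
    "write_bedgraph",
    "read_gff3",
    "write_gff3",
    "read_methylation_tsv",
    "write_methylation_tsv",
    "sites_from_frame",
    "frame_from_sites",
    "read_bed",
    "write_bed",
    "read_breakpoints",
    "write_breakpoints",
]

_GT_TO_CLASS = {
    (0, 0): AlleleClass.HOM_REF,
    (0, 1): AlleleClass.HET,
    (1, 0): AlleleClass.HET,
    (1, 1): AlleleClass.HOM_ALT,
    (None, None): AlleleClass.MISSING,
    (None,): AlleleClass.MISSING,
}


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _support_value(fmt, key: str) -> int:
    value = fmt.get(key)
    if value is None:
        return 0
    if isinstance(value, (tuple, list)):
        value = value[0] if value and value[0] is not None else 0
    return int(value)


def read_sv_vcf(
    path: str | os.PathLike,
    cohort: CohortModel,
    support_fields: tuple[str, str] = ("DR", "DV"),
) -> list[SVRecord]:
    """Read a merged multi-sample SV VCF into :class:`SVRecord` objects.

    ``support_fields`` names the (ref, alt) per-sample read-support FORMAT
    keys; the default is the sniffles DR/DV dialect, and AD-style callers can
    be mapped by passing e.g. ``("RO", "AO")``.  Records whose SVTYPE is not
    INS or DEL are returned as-is (``is_indel`` False) so downstream filters
    can count them as excluded rather than losing them silently.
    """
    ref_key, alt_key = support_fields
    with pysam.VariantFile(os.fspath(path)) as vcf:
        for key in ("GT", ref_key, alt_key):
            if key not in vcf.header.formats:
                raise FormatError(f"VCF FORMAT is missing required key {key!r}")
        for key in ("SVTYPE", "SVLEN"):
            if key not in vcf.header.info:
                raise FormatError(f"VCF INFO is missing required key {key!r}")
        cohort.validate_samples(vcf.header.samples)

        records: list[SVRecord] = []
        for rec in vcf:
            if rec.alts is not None and len(rec.alts) > 1:
                raise FormatError(
                    f"multi-allelic row at {rec.chrom}:{rec.pos} "
                    "(forced-calling output must be biallelic)"
                )
            sv_type = rec.info.get("SVTYPE")
            if sv_type is None:
                raise FormatError(f"row {rec.chrom}:{rec.pos} lacks INFO/SVTYPE")
            if isinstance(sv_type, (tuple, list)):
                sv_type = sv_type[0]
            svlen = rec.info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0] if svlen else None
            sv_length = abs(int(svlen)) if svlen not in (None, 0) else None
            precise = bool(rec.info.get("PRECISE", False)) and not bool(
                rec.info.get("IMPRECISE", False)
            )
            calls: dict[str, GenotypeCall] = {}
            for sample in cohort.samples:
                fmt = rec.samples[sample]
                gt = fmt.get("GT")
                allele_class = _GT_TO_CLASS.get(tuple(gt) if gt else (None,))
                if allele_class is None:
                    raise FormatError(
                        f"unsupported genotype {gt} for {sample} at "
                        f"{rec.chrom}:{rec.pos}"
                    )
                calls[sample] = GenotypeCall(
                    allele_class,
                    ref_reads=_support_value(fmt, ref_key),
                    alt_reads=_support_value(fmt, alt_key),
                )
            records.append(
                SVRecord(
                    id=rec.id or f"{rec.chrom}_{rec.pos}",
                    chrom=rec.chrom,
                    pos=rec.pos,
                    sv_type=str(sv_type),
                    sv_length=sv_length,
                    precise=precise,
                    calls=calls,
                )
            )
    return records


def write_sv_vcf(
    records: Sequence[SVRecord],
    cohort: CohortModel,
    path: str | os.PathLike,
) -> None:
    """Write records in the same VCF 4.2 / DR-DV dialect the reader accepts."""
    header = pysam.VariantHeader()
    for chrom, length in cohort.chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.info.add("SVTYPE", 1, "String", "Type of structural variant")
    header.info.add("SVLEN", 1, "Integer", "Length of structural variant")
    header.info.add("PRECISE", 0, "Flag", "Precise breakpoints")
    header.info.add("IMPRECISE", 0, "Flag", "Imprecise breakpoints")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DR", 1, "Integer", "Reads supporting the reference allele")
    header.formats.add("DV", 1, "Integer", "Reads supporting the variant allele")
    for sample in cohort.samples:
        header.add_sample(sample)

    _class_to_gt = {
        AlleleClass.HOM_REF: (0, 0),
        AlleleClass.HET: (0, 1),
        AlleleClass.HOM_ALT: (1, 1),
        AlleleClass.MISSING: (None, None),
    }
    with pysam.VariantFile(os.fspath(path), "w", header=header) as out:
        for rec in records:
            row = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos,
                alleles=("N", f"<{rec.sv_type}>"),
                id=rec.id,
            )
            row.info["SVTYPE"] = rec.sv_type
            if rec.sv_length is not None:
                row.info["SVLEN"] = rec.sv_length
            if rec.precise:
                row.info["PRECISE"] = True
            else:
                row.info["IMPRECISE"] = True
            for sample in cohort.samples:
                call = rec.calls[sample]
                row.samples[sample]["GT"] = _class_to_gt[call.allele_class]
                row.samples[sample]["DR"] = call.ref_reads
                row.samples[sample]["DV"] = call.alt_reads
            out.write(row)


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def read_bedgraph(
    path: str | os.PathLike,
    chrom_lengths: Mapping[str, int],
    bin_size: int,
    sample: str,
) -> dict[str, CoverageTrack]:
    """Average a per-base bedGraph into fixed bins, one track per chromosome.

    Intervals are 0-based half-open and must not extend beyond the declared
    chromosome length.  Bin values are per-base means; the final partial bin
    is averaged over its true width.  Chromosomes with no intervals get an
    all-zero track.
    """
    df = pd.read_csv(
        os.fspath(path),
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    sums: dict[str, np.ndarray] = {
        chrom: np.zeros(math.ceil(length / bin_size))
        for chrom, length in chrom_lengths.items()
    }
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in chrom_lengths:
            raise CoordinateError(f"bedGraph chromosome {chrom!r} not declared")
        if start < 0 or end > chrom_lengths[chrom] or start >= end:
            raise CoordinateError(
                f"bedGraph interval {chrom}:{start}-{end} outside chromosome bounds"
            )
        first, last = int(start) // bin_size, (int(end) - 1) // bin_size
        acc = sums[chrom]
        for b in range(first, last + 1):
            lo = max(start, b * bin_size)
            hi = min(end, (b + 1) * bin_size)
            acc[b] += value * (hi - lo)

    tracks = {}
    for chrom, acc in sums.items():
        length = chrom_lengths[chrom]
        widths = np.full(len(acc), bin_size, dtype=float)
        widths[-1] = length - (len(acc) - 1) * bin_size
        tracks[chrom] = CoverageTrack(sample, chrom, bin_size, length, acc / widths)
    return tracks


def write_bedgraph(
    tracks: Mapping[str, CoverageTrack] | Iterable[CoverageTrack],
    path: str | os.PathLike,
) -> None:
    """Write one bedGraph line per bin (0-based half-open)."""
    if isinstance(tracks, Mapping):
        tracks = tracks.values()
    with open(os.fspath(path), "w") as out:
        for track in tracks:
            starts = track.bin_starts()
            for i, depth in enumerate(track.depths):
                end = min(int(starts[i]) + track.bin_size, track.chrom_length)
                out.write(f"{track.chrom}\t{int(starts[i])}\t{end}\t{depth:g}\n")


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene/exon features from GFF3 (1-based inclusive) into 0-based
    half-open :class:`GeneModel` objects."""
    try:
        db = gffutils.create_db(
            os.fspath(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"could not parse GFF3 {path}: {exc}") from exc
    genes = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [
            GenomicInterval(exon.seqid, exon.start - 1, exon.end)
            for exon in db.children(gene, featuretype="exon", order_by="start")
        ]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                interval=GenomicInterval(gene.seqid, gene.start - 1, gene.end),
                strand=gene.strand,
                exons=exons,
            )
        )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as out:
        out.write("##gff-version 3\n")
        for gene in genes:
            iv = gene.interval
            out.write(
                f"{iv.chrom}\thomeox\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for k, exon in enumerate(gene.exons, 1):
                out.write(
                    f"{exon.chrom}\thomeox\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{gene.strand}\t.\tID={gene.gene_id}.exon{k};"
                    f"Parent={gene.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# methylation tables
# ---------------------------------------------------------------------------

def read_methylation_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-cytosine methylation frequency table.

    Dialect: tab-separated, one '#'-prefixed header line, columns
    ``sample chrom pos strand context n_meth n_total frequency`` with 0-based
    positions.  Returns a DataFrame in :data:`~homeox.models.SITE_COLUMNS`
    order; the reported frequency is validated against n_meth/n_total.
    """
    df = pd.read_csv(os.fspath(path), sep="\t", dtype={"chrom": str, "sample": str})
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"methylation TSV is missing columns {missing}")
    df = df[SITE_COLUMNS].copy()
    bad = (df["n_meth"] < 0) | (df["n_meth"] > df["n_total"])
    if bad.any():
        line = int(df.index[bad][0]) + 2  # 1-based, after header
        raise FormatError(f"methylation TSV line {line}: n_meth outside [0, n_total]")
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = np.where(df["n_total"] > 0, df["n_meth"] / df["n_total"], 0.0)
    if not np.allclose(df["frequency"], expected, atol=1e-9):
        line = int(np.argmax(~np.isclose(df["frequency"], expected, atol=1e-9))) + 2
        raise FormatError(
            f"methylation TSV line {line}: frequency inconsistent with counts"
        )
    return df


def write_methylation_tsv(sites: pd.DataFrame, path: str | os.PathLike) -> None:
    df = sites[SITE_COLUMNS].copy()
    with open(os.fspath(path), "w") as out:
        out.write("#" + "\t".join(SITE_COLUMNS) + "\n")
        df.to_csv(out, sep="\t", header=False, index=False, float_format="%.10g")


def sites_from_frame(df: pd.DataFrame) -> list[MethylationSite]:
    return [
        MethylationSite(
            sample=row.sample,
            chrom=row.chrom,
            pos=int(row.pos),
            strand=row.strand,
            context=row.context,
            n_meth=int(row.n_meth),
            n_total=int(row.n_total),
        )
        for row in df.itertuples(index=False)
    ]


def frame_from_sites(sites: Iterable[MethylationSite]) -> pd.DataFrame:
    rows = [
        (s.sample, s.chrom, s.pos, s.strand, s.context, s.n_meth, s.n_total, s.frequency)
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


# ---------------------------------------------------------------------------
# BED intervals and breakpoint lists
# ---------------------------------------------------------------------------

def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    df = pd.read_csv(
        os.fspath(path),
        sep="\t",
        comment="#",
        header=None,
        usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str},
    )
    return [
        GenomicInterval(row.chrom, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    ]


def write_bed(intervals: Sequence[GenomicInterval], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as out:
        for iv in intervals:
            out.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_breakpoints(path: str | os.PathLike) -> dict[str, list[int]]:
    """Scaffold-join breakpoints as a two-column (chrom, pos) TSV."""
    df = pd.read_csv(
        os.fspath(path),
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "pos"],
        dtype={"chrom": str},
    )
    out: dict[str, list[int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.chrom, []).append(int(row.pos))
    return {chrom: sorted(pos) for chrom, pos in out.items()}


def write_breakpoints(
    breakpoints: Mapping[str, Sequence[int]], path: str | os.PathLike
) -> None:
    with open(os.fspath(path), "w") as out:
        for chrom in breakpoints:
            for pos in breakpoints[chrom]:
                out.write(f"{chrom}\t{pos}\n")
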