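"""Bin-wise differential methylation against the paternal parent.

Per-cytosine methylation observations (reads supporting methylation /
total reads, per CpG/CHG/CHH context) are aggregated into fixed 1000 bp
bins and each F1 is contrasted against the control parent with a
two-proportion score test: with pooled proportion
``p = (m1 + m2) / (n1 + n2)``,

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)),

whose square is the Pearson chi-square statistic of the 2x2 table without
continuity correction.  A bin is differentially methylated when both
samples cover at least ``min_cc`` cytosines, the proportion difference
reaches ``min_diff`` and the two-sided p-value is below ``p_threshold``
(raw, no multiplicity correction by default — an optional
Benjamini-Hochberg mode is provided).  Adjacent significant bins of the
same direction merge when separated by at most ``min_gap`` bp (0 = only
directly abutting bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .errors import AlignmentError, ConfigError, UndefinedTestError
from .models import GeneModel, GenomicInterval

__all__ = [
    "DmrParams",
    "aggregate_bins",
    "count_methylated_cytosines",
    "score_test",
    "call_dmrs",
    "annotate_dmrs",
]

BIN_COLUMNS = ["chrom", "start", "end", "n_cytosines", "n_meth", "n_total", "proportion"]


@dataclass
class DmrParams:
    """DMR-calling thresholds (defaults: 1000 bp bins, minimum cytosine
    count 4, proportion difference 0.4, p < 0.01, gap 0)."""

    bin_size: int = 1000
    p_threshold: float = 0.01
    min_cc: int = 4
    min_diff: float = 0.4
    min_gap: int = 0
    fdr: bool = False  # Benjamini-Hochberg on bin p-values before thresholding

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")
        if not 0 < self.p_threshold < 1:
            raise ConfigError("p_threshold must lie in (0, 1)")
        if not 0 <= self.min_diff <= 1:
            raise ConfigError("min_diff must lie in [0, 1]")


def aggregate_bins(
    sites: pd.DataFrame,
    bin_size: int = 1000,
    context: str | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate one sample's cytosine sites into fixed bins.

    Returns a frame with covered-cytosine counts and summed read counts per
    bin; ``proportion`` is NaN for bins without reads.  When
    ``chrom_lengths`` is given the full (possibly empty-bin) grid is
    produced, otherwise only bins containing at least one site.
    """
    df = sites
    if context is not None:
        df = df[df["context"] == context]
    if df["sample"].nunique() > 1:
        raise ConfigError("aggregate_bins expects sites from a single sample")
    df = df.assign(bin=df["pos"] // bin_size)
    grouped = (
        df.groupby(["chrom", "bin"], sort=True)
        .agg(n_cytosines=("pos", "size"), n_meth=("n_meth", "sum"),
             n_total=("n_total", "sum"))
        .reset_index()
    )
    if chrom_lengths is not None:
        grids = []
        for chrom, length in chrom_lengths.items():
            n_bins = -(-length // bin_size)
            grids.append(pd.DataFrame({"chrom": chrom, "bin": np.arange(n_bins)}))
        grid = pd.concat(grids, ignore_index=True)
        grouped = grid.merge(grouped, on=["chrom", "bin"], how="left").fillna(
            {"n_cytosines": 0, "n_meth": 0, "n_total": 0}
        )
        for col in ("n_cytosines", "n_meth", "n_total"):
            grouped[col] = grouped[col].astype(int)
    grouped["start"] = grouped["bin"] * bin_size
    grouped["end"] = grouped["start"] + bin_size
    if chrom_lengths is not None:
        ends = grouped["chrom"].map(dict(chrom_lengths))
        grouped["end"] = np.minimum(grouped["end"], ends)
    with np.errstate(invalid="ignore", divide="ignore"):
        grouped["proportion"] = np.where(
            grouped["n_total"] > 0, grouped["n_meth"] / grouped["n_total"], np.nan
        )
    return grouped[BIN_COLUMNS]


def count_methylated_cytosines(
    sites: pd.DataFrame,
    freq_threshold: float = 0.5,
    min_site_cov: int = 4,
) -> int:
    """Number of cytosines called methylated: frequency strictly above the
    threshold at sufficient per-site coverage."""
    ok = (sites["frequency"] > freq_threshold) & (sites["n_total"] >= min_site_cov)
    return int(ok.sum())


def score_test(m1, n1, m2, n2):
    """Two-proportion score test; returns ``(z, p)``.

    Vectorised over array inputs.  A degenerate pooled proportion (0 or 1)
    gives z = 0, p = 1.  Raises :class:`UndefinedTestError` when any margin
    is zero.
    """
    m1, n1 = np.asarray(m1, dtype=float), np.asarray(n1, dtype=float)
    m2, n2 = np.asarray(m2, dtype=float), np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise UndefinedTestError("score test undefined for n = 0")
    pooled = (m1 + m2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, (m1 / n1 - m2 / n2) / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(se > 0, 2 * stats.norm.sf(np.abs(z)), 1.0)
    if z.ndim == 0:
        return float(z), float(p)
    return z, p


def call_dmrs(
    f1_bins: pd.DataFrame,
    control_bins: pd.DataFrame,
    params: DmrParams | None = None,
    context: str | None = None,
) -> pd.DataFrame:
    """Call DMRs of one F1 sample against the control parent.

    Both inputs come from :func:`aggregate_bins` on the same grid (a bin
    start that is not a multiple of the bin size raises
    :class:`AlignmentError`).  Only bins covered in both samples are
    testable.  Returns one row per merged DMR with direction (``hypo`` when
    the F1 proportion is below the control), the smallest member-bin
    p-value and pooled proportions/cytosine counts over the merged extent.
    """
    params = params or DmrParams()
    for df in (f1_bins, control_bins):
        if len(df) and np.any(df["start"].to_numpy() % params.bin_size):
            raise AlignmentError(
                f"bin starts are not aligned to the {params.bin_size} bp grid"
            )
    merged = f1_bins.merge(
        control_bins, on=["chrom", "start", "end"], suffixes=("_f1", "_ctrl")
    )
    testable = merged[
        (merged["n_cytosines_f1"] >= params.min_cc)
        & (merged["n_cytosines_ctrl"] >= params.min_cc)
        & (merged["n_total_f1"] > 0)
        & (merged["n_total_ctrl"] > 0)
    ].copy()
    if not len(testable):
        return _empty_dmr_frame(context)
    z, p = score_test(
        testable["n_meth_f1"].to_numpy(),
        testable["n_total_f1"].to_numpy(),
        testable["n_meth_ctrl"].to_numpy(),
        testable["n_total_ctrl"].to_numpy(),
    )
    if params.fdr:
        p = stats.false_discovery_control(p, method="bh")
    testable["p_value"] = p
    testable["diff"] = testable["proportion_f1"] - testable["proportion_ctrl"]
    hits = testable[
        (testable["p_value"] < params.p_threshold)
        & (testable["diff"].abs() >= params.min_diff)
    ].sort_values(["chrom", "start"])
    if not len(hits):
        return _empty_dmr_frame(context)

    rows = []
    current: dict | None = None
    for row in hits.itertuples(index=False):
        direction = "hypo" if row.diff < 0 else "hyper"
        if (
            current is not None
            and row.chrom == current["chrom"]
            and current["direction"] == direction
            and row.start - current["end"] <= params.min_gap
        ):
            current["end"] = row.end
            current["p_value"] = min(current["p_value"], row.p_value)
            for key, val in (
                ("n_meth_f1", row.n_meth_f1),
                ("n_total_f1", row.n_total_f1),
                ("n_meth_ctrl", row.n_meth_ctrl),
                ("n_total_ctrl", row.n_total_ctrl),
                ("n_cytosines_f1", row.n_cytosines_f1),
                ("n_cytosines_ctrl", row.n_cytosines_ctrl),
            ):
                current[key] += val
        else:
            if current is not None:
                rows.append(current)
            current = {
                "chrom": row.chrom,
                "start": int(row.start),
                "end": int(row.end),
                "direction": direction,
                "p_value": float(row.p_value),
                "n_meth_f1": row.n_meth_f1,
                "n_total_f1": row.n_total_f1,
                "n_meth_ctrl": row.n_meth_ctrl,
                "n_total_ctrl": row.n_total_ctrl,
                "n_cytosines_f1": row.n_cytosines_f1,
                "n_cytosines_ctrl": row.n_cytosines_ctrl,
            }
    rows.append(current)
    out = pd.DataFrame(rows)
    out["proportion_f1"] = out["n_meth_f1"] / out["n_total_f1"]
    out["proportion_ctrl"] = out["n_meth_ctrl"] / out["n_total_ctrl"]
    out["context"] = context
    return out[
        [
            "chrom", "start", "end", "context", "direction", "p_value",
            "proportion_f1", "proportion_ctrl",
            "n_cytosines_f1", "n_cytosines_ctrl",
        ]
    ]


def _empty_dmr_frame(context: str | None) -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "chrom", "start", "end", "context", "direction", "p_value",
            "proportion_f1", "proportion_ctrl",
            "n_cytosines_f1", "n_cytosines_ctrl",
        ]
    )


def annotate_dmrs(
    dmrs: pd.DataFrame,
    genes: Sequence[GeneModel],
    repeats: Sequence[GenomicInterval],
    chrom_lengths: Mapping[str, int],
    promoter_width: int = 1000,
) -> pd.DataFrame:
    """Flag feature overlaps and the distance to the nearest gene.

    Features: exon; intron (gene body minus exons); repeat; promoter (a
    strand-aware window of ``promoter_width`` bp upstream of the gene
    start, clipped to the chromosome).  ``nearest_gene_bp`` is 0 for a DMR
    overlapping any gene, otherwise the gap to the closest gene body.
    """
    exon_trees: dict[str, IntervalTree] = {}
    intron_trees: dict[str, IntervalTree] = {}
    promoter_trees: dict[str, IntervalTree] = {}
    gene_bounds: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        chrom = gene.interval.chrom
        gene_bounds.setdefault(chrom, []).append(
            (gene.interval.start, gene.interval.end)
        )
        tree = exon_trees.setdefault(chrom, IntervalTree())
        cursor = gene.interval.start
        introns = intron_trees.setdefault(chrom, IntervalTree())
        for exon in gene.exons:
            tree[exon.start:exon.end] = gene.gene_id
            if exon.start > cursor:
                introns[cursor:exon.start] = gene.gene_id
            cursor = exon.end
        if cursor < gene.interval.end:
            introns[cursor:gene.interval.end] = gene.gene_id
        if not gene.exons:  # exonless model: whole body counts as intron
            introns[gene.interval.start:gene.interval.end] = gene.gene_id
        promoter = gene.promoter(chrom_lengths[chrom], promoter_width)
        if promoter is not None:
            promoter_trees.setdefault(chrom, IntervalTree())[
                promoter.start:promoter.end
            ] = gene.gene_id
    repeat_trees: dict[str, IntervalTree] = {}
    for iv in repeats:
        repeat_trees.setdefault(iv.chrom, IntervalTree())[iv.start:iv.end] = True

    out = dmrs.copy()
    flags = {"exon": [], "intron": [], "repeat": [], "promoter": []}
    nearest = []
    for row in dmrs.itertuples(index=False):
        chrom, start, end = row.chrom, int(row.start), int(row.end)
        flags["exon"].append(bool(exon_trees.get(chrom, IntervalTree())[start:end]))
        flags["intron"].append(
            bool(intron_trees.get(chrom, IntervalTree())[start:end])
        )
        flags["repeat"].append(
            bool(repeat_trees.get(chrom, IntervalTree())[start:end])
        )
        flags["promoter"].append(
            bool(promoter_trees.get(chrom, IntervalTree())[start:end])
        )
        bounds = gene_bounds.get(chrom, [])
        if not bounds:
            nearest.append(np.nan)
        else:
            dist = min(
                0 if (start < ge and gs < end) else
                (gs - end if end <= gs else start - ge)
                for gs, ge in bounds
            )
            nearest.append(max(0, dist))
    for name, values in flags.items():
        out[f"in_{name}"] = values
    out["nearest_gene_bp"] = nearest
    return out
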