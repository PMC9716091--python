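"""Ortholog-hit filtering and gene copy-number tallies.

The ortholog rule assigns each query gene at most one functional homolog
from a tabular (BLAST outfmt-6-like) search: hits must have e-value below
1e-4, no gap opens and at least 90% identity; among survivors the lowest
e-value wins, ties going to the first reported hit.  The CNV tally counts
genes overlapping each deletion / refined duplication interval and sums
them over the cohort (a gene deleted in two siblings counts twice — the
totals measure gene-copy events, not distinct genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import FormatError
from .models import GeneModel, GenomicInterval

__all__ = [
    "OUTFMT6_COLUMNS",
    "OrthologFilterParams",
    "CNVTally",
    "filter_ortholog_hits",
    "tally_gene_cnv",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass
class OrthologFilterParams:
    max_evalue: float = 1e-4  # exclusive
    max_gap_opens: int = 0
    min_identity: float = 90.0  # inclusive


def filter_ortholog_hits(
    hits: pd.DataFrame, params: OrthologFilterParams | None = None
) -> pd.DataFrame:
    """Best qualifying hit per query gene.

    ``hits`` needs at least the columns qseqid, sseqid, pident, gapopen,
    evalue (outfmt-6 naming).  Idempotent: re-filtering the output returns
    it unchanged.
    """
    params = params or OrthologFilterParams()
    required = {"qseqid", "sseqid", "pident", "gapopen", "evalue"}
    missing = required - set(hits.columns)
    if missing:
        raise FormatError(f"hit table is missing columns {sorted(missing)}")
    ok = hits[
        (hits["evalue"] < params.max_evalue)
        & (hits["gapopen"] <= params.max_gap_opens)
        & (hits["pident"] >= params.min_identity)
    ]
    # stable sort keeps input order among equal e-values: first hit wins
    best = (
        ok.sort_values("evalue", kind="stable")
        .drop_duplicates("qseqid", keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    return best


@dataclass
class CNVTally:
    """Per-event and cohort-total deleted/duplicated gene counts."""

    per_event: list[dict] = field(default_factory=list)
    total_deleted: int = 0
    total_duplicated: int = 0


def _genes_in(
    interval: GenomicInterval, genes: Sequence[GeneModel], overlap_frac: float
) -> list[str]:
    hits = []
    for gene in genes:
        ov = gene.interval.overlap_length(interval)
        if ov >= overlap_frac * gene.interval.length:
            hits.append(gene.gene_id)
    return hits


def tally_gene_cnv(
    deletions: Sequence[tuple[str, GenomicInterval]],
    duplications: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[GeneModel],
    overlap_frac: float = 0.5,
) -> CNVTally:
    """Count genes hit by each (sample, interval) deletion / duplication.

    A gene counts when at least ``overlap_frac`` of its body lies inside
    the event interval.  Totals are additive over events and independent
    of event order.
    """
    tally = CNVTally()
    for sample, interval in deletions:
        ids = _genes_in(interval, genes, overlap_frac)
        tally.per_event.append(
            {
                "sample": sample,
                "chrom": interval.chrom,
                "start": interval.start,
                "end": interval.end,
                "kind": "DEL",
                "n_genes": len(ids),
                "genes": ids,
            }
        )
        tally.total_deleted += len(ids)
    for sample, interval in duplications:
        ids = _genes_in(interval, genes, overlap_frac)
        tally.per_event.append(
            {
                "sample": sample,
                "chrom": interval.chrom,
                "start": interval.start,
                "end": interval.end,
                "kind": "DUP",
                "n_genes": len(ids),
                "genes": ids,
            }
        )
        tally.total_duplicated += len(ids)
    return tally
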