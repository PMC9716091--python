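"""Published geometry of the Express 617 x G3D001 F1 rearrangement study.

The five large spontaneous rearrangements reported for that *Brassica napus*
cross (two segmental deletions, three non-reciprocal homoeologous exchanges)
are bundled here as plain numbers: per-event chromosome, carrier F1 plants,
chromosome/segment coverage, printed start/end coordinates in Mbp and the
counts of mid-sized SV alleles and of deleted/duplicated genes.  They serve
two purposes: in-table arithmetic checks (interval lengths, cohort gene-CNV
totals) and the default event set the synthetic cohort generator plants at a
1:4 desk scale.
"""

from __future__ import annotations

import pandas as pd

from .models import GenomicInterval

__all__ = [
    "REARRANGEMENT_TABLE",
    "SCALE",
    "REAL_CHROM_LENGTHS_MBP",
    "HOMOEOLOG_PARTNERS",
    "CENTROMERE_FRACTION",
    "scaled_chrom_lengths",
    "reference_events",
    "table_lengths_mbp",
    "gene_cnv_totals",
]

#: one row per reported rearrangement; coordinates exactly as printed (Mbp)
REARRANGEMENT_TABLE = pd.DataFrame(
    [
        # chrom, carriers,          chrom_cov, seg_cov, start, end,   length, AA, AB, BB,  del, dup,  type
        ("A09", ("F1_06",),         40.35, 22.07, 39.00, 40.20, 1.20, 0, 0, 64, 261, 422, "NRHE"),
        ("A10", ("F1_05",),         40.46, 22.07, 18.82, 20.49, 1.67, 0, 0, 107, 447, 261, "NRHE"),
        ("C01", ("F1_02", "F1_03", "F1_04"),
                                    46.06, 19.84, 18.70, 20.70, 2.00, 0, 0, 31, 108, None, "SEG_DEL"),
        ("C03", ("F1_02",),         38.45, 22.58, 3.65, 13.60, 9.95, 0, 0, 228, 1852, None, "SEG_DEL"),
        ("C08", ("F1_01",),         40.05, 21.11, 48.20, 52.06, 3.87, 0, 0, 87, 754, 736, "NRHE"),
    ],
    columns=[
        "chrom", "carriers", "chrom_cov", "seg_cov", "start_mbp", "end_mbp",
        "length_mbp", "n_aa", "n_ab", "n_bb", "genes_del", "genes_dup",
        "rearrangement_type",
    ],
)

#: desk-scale shrink factor applied to all coordinates
SCALE = 0.25

#: assumed full-scale chromosome lengths (Mbp); chosen so every reported
#: event fits and its qualitative chromosome location (telomeric for
#: A09/A10/C03/C08, pericentromeric for C01) is preserved after scaling
REAL_CHROM_LENGTHS_MBP = {
    "A01": 24.0,
    "A03": 32.0,
    "A09": 44.0,
    "A10": 22.5,
    "C01": 25.0,
    "C03": 60.0,
    "C08": 57.0,
    "C09": 50.0,
}

#: homoeologous chromosome partnerships between the A and C subgenomes
HOMOEOLOG_PARTNERS = {
    "A01": "C01",
    "A03": "C03",
    "A09": "C08",
    "A10": "C09",
}
HOMOEOLOG_PARTNERS.update({c: a for a, c in list(HOMOEOLOG_PARTNERS.items())})

#: centromere position as a fraction of chromosome length; C01 is placed so
#: the reported C01 deletion lies pericentromerically
CENTROMERE_FRACTION = {chrom: 0.40 for chrom in REAL_CHROM_LENGTHS_MBP}
CENTROMERE_FRACTION["C01"] = 0.74


def scaled_chrom_lengths(scale: float = SCALE) -> dict[str, int]:
    return {
        chrom: int(round(mbp * 1e6 * scale))
        for chrom, mbp in REAL_CHROM_LENGTHS_MBP.items()
    }


def table_lengths_mbp() -> pd.Series:
    """Event lengths recomputed from the printed start/end coordinates."""
    return (REARRANGEMENT_TABLE["end_mbp"] - REARRANGEMENT_TABLE["start_mbp"]).round(2)


def gene_cnv_totals() -> tuple[int, int]:
    """Cohort totals of deleted and duplicated genes across the five events."""
    deleted = int(REARRANGEMENT_TABLE["genes_del"].sum())
    duplicated = int(REARRANGEMENT_TABLE["genes_dup"].dropna().sum())
    return deleted, duplicated


def _colinear_image(
    interval: GenomicInterval, partner: str, lengths: dict[str, int]
) -> GenomicInterval:
    """Map an interval to the same fractional position on the homoeologous
    partner chromosome (the generator places homoeologous genes colinearly)."""
    src_len = lengths[interval.chrom]
    dst_len = lengths[partner]
    start = int(round(interval.start / src_len * dst_len))
    end = int(round(interval.end / src_len * dst_len))
    return GenomicInterval(partner, start, max(end, start + 1))


def reference_events(scale: float = SCALE):
    """The five reported rearrangements as desk-scale planted events.

    Returns one event per (region, carrier): the C01 deletion is shared by
    three F1 plants, so seven events describe the five rearranged regions.
    For NRHE rows the duplicated counterpart is placed at the colinear
    position on the homoeologous partner chromosome.
    """
    from .simulate import EventSpec  # local import to avoid a cycle

    lengths = scaled_chrom_lengths(scale)
    events = []
    for row in REARRANGEMENT_TABLE.itertuples(index=False):
        del_iv = GenomicInterval(
            row.chrom,
            int(round(row.start_mbp * 1e6 * scale)),
            int(round(row.end_mbp * 1e6 * scale)),
        )
        dup_iv = None
        if row.rearrangement_type == "NRHE":
            dup_iv = _colinear_image(del_iv, HOMOEOLOG_PARTNERS[row.chrom], lengths)
        for carrier in row.carriers:
            events.append(
                EventSpec(
                    event_type=row.rearrangement_type,
                    carrier=carrier,
                    del_interval=del_iv,
                    dup_interval=dup_iv,
                )
            )
    return events
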