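"""Post-calling SV filter cascade and non-Mendelian selection.

The cascade isolates high-confidence insertions/deletions from a merged,
forced-called multi-sample VCF and then keeps only variants whose allele
classes differ *between* F1 siblings — the signature of a spontaneous
rearrangement in a cross whose offspring should be uniformly heterozygous.

Stages (each a per-record predicate, applied in a fixed order but
order-independent by construction):

1.  ``sv_type``           SVTYPE is INS or DEL
2.  ``min_length``        resolved length strictly greater than ``min_len``
3.  ``min_support``       called-allele read support reaches ``min_support``
                          (by default in at least one sample — the caller's
                          discovery threshold; set ``support_mode='all'`` to
                          demand it in every sample)
4.  ``precise``           breakpoints flagged precise
5.  ``resolved_length``   insertions must have a resolved length
6.  ``paternal_hom_alt``  the paternal parent is homozygous alternate
7.  ``max_length``        length strictly smaller than ``max_len``
8.  ``no_missing``        no sample has a missing genotype
9.  ``allele_support``    every sample's read fractions are consistent with
                          its called class (>= 90% for homozygotes, a
                          symmetric window around 0.5 for heterozygotes)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

from .errors import CohortError, ConfigError, SupportError
from .models import AlleleClass, CohortModel, GenotypeCall, SVRecord

__all__ = [
    "FilterParams",
    "FilterReport",
    "DivergentCall",
    "allele_support_ok",
    "filter_cascade",
    "divergent_among_f1",
    "STAGE_NAMES",
]


@dataclass
class FilterParams:
    """Thresholds of the cascade (defaults follow the published pipeline:
    length > 30 bp, support >= 25 reads, length < 50 kbp, >= 90% of reads
    supporting the predicted allele)."""

    min_len: int = 30  # exclusive
    min_support: int = 25
    max_len: int = 50_000  # exclusive
    min_allele_fraction: float = 0.90
    het_fraction_window: tuple[float, float] = (0.25, 0.75)
    support_mode: str = "any"  # "any" | "all"

    def __post_init__(self) -> None:
        if not 0 < self.min_len < self.max_len:
            raise ConfigError("require 0 < min_len < max_len")
        if not 0.5 < self.min_allele_fraction <= 1.0:
            raise ConfigError("min_allele_fraction must lie in (0.5, 1]")
        lo, hi = self.het_fraction_window
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigError("het_fraction_window must satisfy 0 <= lo < hi <= 1")
        if self.support_mode not in ("any", "all"):
            raise ConfigError("support_mode must be 'any' or 'all'")


@dataclass
class FilterReport:
    """Audit trail of the cascade: per-stage in/out counts plus, for every
    excluded record, the stage that removed it."""

    stage_counts: list[tuple[str, int, int]] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)

    @property
    def n_in(self) -> int:
        return self.stage_counts[0][1] if self.stage_counts else 0

    @property
    def n_out(self) -> int:
        return self.stage_counts[-1][2] if self.stage_counts else 0

    def counts_by_stage(self) -> dict[str, int]:
        """Number of records each stage excluded."""
        return {
            name: n_in - n_out for name, n_in, n_out in self.stage_counts
        }


def allele_support_ok(call: GenotypeCall, params: FilterParams) -> bool:
    """Does the read-support fraction back the called allele class?

    Homozygous calls need ``min_allele_fraction`` of reads on the called
    allele; heterozygous calls need an alt fraction inside
    ``het_fraction_window`` (the >=90% rule is ill-posed for a heterozygote,
    where the expectation is one read in two).  MISSING is never ok.
    """
    if call.allele_class is AlleleClass.MISSING:
        return False
    if call.total_reads == 0:
        raise SupportError(
            f"zero supporting reads for a called {call.allele_class.name} genotype"
        )
    if call.allele_class is AlleleClass.HOM_ALT:
        return call.alt_fraction >= params.min_allele_fraction
    if call.allele_class is AlleleClass.HOM_REF:
        return 1.0 - call.alt_fraction >= params.min_allele_fraction
    lo, hi = params.het_fraction_window
    return lo <= call.alt_fraction <= hi


def _support_reached(rec: SVRecord, cohort: CohortModel, params: FilterParams) -> bool:
    supports = [rec.calls[s].called_allele_support for s in cohort.samples]
    if params.support_mode == "all":
        return all(s >= params.min_support for s in supports)
    return any(s >= params.min_support for s in supports)


def _stages(
    cohort: CohortModel, params: FilterParams
) -> list[tuple[str, Callable[[SVRecord], bool]]]:
    def all_support_ok(rec: SVRecord) -> bool:
        return all(
            rec.calls[s].allele_class is not AlleleClass.MISSING
            and allele_support_ok(rec.calls[s], params)
            for s in cohort.samples
        )

    return [
        ("sv_type", lambda r: r.is_indel),
        ("min_length", lambda r: r.sv_length is None or r.sv_length > params.min_len),
        ("min_support", lambda r: _support_reached(r, cohort, params)),
        ("precise", lambda r: r.precise),
        (
            "resolved_length",
            lambda r: not (r.sv_type == "INS" and r.sv_length is None),
        ),
        (
            "paternal_hom_alt",
            lambda r: r.calls[cohort.paternal].allele_class is AlleleClass.HOM_ALT,
        ),
        ("max_length", lambda r: r.sv_length is not None and r.sv_length < params.max_len),
        (
            "no_missing",
            lambda r: all(
                r.calls[s].allele_class is not AlleleClass.MISSING
                for s in cohort.samples
            ),
        ),
        ("allele_support", all_support_ok),
    ]


STAGE_NAMES = [name for name, _ in _stages(
    CohortModel("M", "P", ["F1"], {"chr": 1}), FilterParams()
)]


def filter_cascade(
    records: Sequence[SVRecord],
    cohort: CohortModel,
    params: FilterParams | None = None,
    stage_order: Sequence[str] | None = None,
) -> tuple[list[SVRecord], FilterReport]:
    """Run the nine-stage cascade; returns survivors plus an audit report.

    ``stage_order`` permutes the stages (all are per-record predicates, so
    the surviving set is order-invariant; only the attribution of exclusion
    reasons shifts).
    """
    params = params or FilterParams()
    stages = dict(_stages(cohort, params))
    order = list(stage_order) if stage_order is not None else list(stages)
    if set(order) != set(stages):
        raise ConfigError(f"stage_order must be a permutation of {list(stages)}")

    report = FilterReport()
    current = list(records)
    for name in order:
        predicate = stages[name]
        kept = []
        n_in = len(current)
        for rec in current:
            if predicate(rec):
                kept.append(rec)
            else:
                report.exclusions[rec.id] = name
        report.stage_counts.append((name, n_in, len(kept)))
        current = kept
    return current, report


@dataclass
class DivergentCall:
    """A high-confidence SV whose allele classes differ among F1 siblings."""

    record: SVRecord
    majority_class: AlleleClass
    deviant_samples: list[str]


def divergent_among_f1(
    records: Sequence[SVRecord], cohort: CohortModel
) -> list[DivergentCall]:
    """Keep records with >= 2 distinct allele classes among the F1 siblings.

    For each kept record the samples deviating from the F1 majority class
    are flagged; ties for the majority are broken toward HET (the Mendelian
    expectation), then by class frequency order.
    """
    if len(cohort.f1_samples) < 2:
        raise CohortError("divergence is undefined with fewer than 2 F1 samples")
    out = []
    for rec in records:
        classes = rec.f1_classes(cohort)
        if len(set(classes)) < 2:
            continue
        counts: dict[AlleleClass, int] = {}
        for cls in classes:
            counts[cls] = counts.get(cls, 0) + 1
        majority = max(
            counts, key=lambda c: (counts[c], c is AlleleClass.HET)
        )
        deviants = [
            s
            for s in cohort.f1_samples
            if rec.calls[s].allele_class is not majority
        ]
        out.append(DivergentCall(rec, majority, deviants))
    return out
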