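"""End-to-end orchestration with a JSON run manifest.

``run_all`` executes the stages

    simulate -> filter-sv -> detect-rearrangements -> detect-hne
             -> call-dmrs -> annotate

from a single configuration mapping (usually loaded from YAML).  Inputs
are either generated by the synthetic cohort module (``simulate: true``,
the default) or read from the configured file paths.  Every stage writes
plain-text TSV artefacts into the output directory, and the manifest
records seeds, parameters and per-stage record counts so any stage can be
re-run in isolation.  All outputs are deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Any, Mapping

import pandas as pd

from . import __version__, reference
from .annotate import filter_ortholog_hits, tally_gene_cnv
from .errors import HomeoxError
from .hne import (
    HneParams,
    call_depth_segments,
    classify_rearrangements,
    match_nrhe,
    refine_nrhe_calls,
    select_pairs,
)
from .methylation import DmrParams, aggregate_bins, annotate_dmrs, call_dmrs
from .models import GenomicInterval
from .rearrangements import (
    DetectionParams,
    detect_rearrangements,
    estimate_centromere,
)
from .simulate import (
    DmrSpec,
    EventSpec,
    SimConfig,
    build_genome_model,
    export_cohort,
    simulate_cohort,
    simulate_methylome,
)
from .svfilter import FilterParams, divergent_among_f1, filter_cascade

__all__ = ["scaled_detection_params", "run_all", "load_config"]


def scaled_detection_params(scale: float = reference.SCALE, **overrides) -> DetectionParams:
    """Detection parameters with the window geometry shrunk by ``scale``
    (1 Mbp windows/event floor and 2 Mbp pericentromeric distance at full
    scale)."""
    kwargs: dict[str, Any] = dict(
        window=int(1_000_000 * scale),
        min_event_len=int(1_000_000 * scale),
        pericen_dist=int(2_000_000 * scale),
    )
    kwargs.update(overrides)
    return DetectionParams(**kwargs)


def load_config(path: str | os.PathLike) -> dict:
    import yaml

    with open(os.fspath(path)) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise HomeoxError(f"run configuration {path} must be a mapping")
    return config


def _events_from_config(config: Mapping) -> list[EventSpec]:
    rows = config.get("events")
    if rows is None:
        return reference.reference_events(config.get("scale", reference.SCALE))
    events = []
    for row in rows:
        dup = None
        if row.get("chrom_dup"):
            dup = GenomicInterval(
                row["chrom_dup"], int(row["dup_start"]), int(row["dup_end"])
            )
        events.append(
            EventSpec(
                event_type=row["event_type"],
                carrier=row["carrier"],
                del_interval=GenomicInterval(
                    row["chrom_del"], int(row["del_start"]), int(row["del_end"])
                ),
                dup_interval=dup,
            )
        )
    return events


def run_all(config: Mapping | None = None, outdir: str | os.PathLike = "homeox_run") -> dict:
    """Run every pipeline stage; returns the manifest (also written as JSON).

    ``config`` keys (all optional): ``seed``, ``scale``, ``events`` (list of
    planted-event rows), ``sim`` (SimConfig overrides), ``filter`` /
    ``detect`` / ``hne`` / ``dmr`` (parameter-block overrides), and
    ``methylation`` (``context``, ``chroms``, ``samples``, ``control``,
    ``planted_dmrs``).
    """
    config = dict(config or {})
    outdir = os.fspath(config.get("outdir", outdir))
    os.makedirs(outdir, exist_ok=True)
    scale = config.get("scale", reference.SCALE)
    seed = int(config.get("seed", 0))

    manifest: dict[str, Any] = {
        "package": "homeox",
        "version": __version__,
        "seed": seed,
        "scale": scale,
        "stages": [],
    }

    # ------------------------------------------------------------ simulate
    sim_cfg = SimConfig(seed=seed, **config.get("sim", {}))
    model = build_genome_model(sim_cfg)
    events = _events_from_config(config)
    tracks, records, truth = simulate_cohort(model, events, sim_cfg)

    meth_cfg = dict(config.get("methylation", {}))
    context = meth_cfg.get("context", "CpG")
    control = meth_cfg.get("control", model.cohort.paternal)
    meth_chroms = meth_cfg.get("chroms", ["C03"])
    meth_samples = meth_cfg.get("samples", ["F1_02"])
    planted_dmrs = [
        DmrSpec(
            carrier=row["carrier"],
            interval=GenomicInterval(
                row["chrom"], int(row["start"]), int(row["end"])
            ),
            context=row.get("context", context),
            delta=float(row["delta"]),
        )
        for row in meth_cfg.get("planted_dmrs", [])
    ]
    methylome = simulate_methylome(
        model,
        events,
        sim_cfg,
        chroms=meth_chroms,
        samples=sorted(set(meth_samples) | {control}),
        dmr_regions=planted_dmrs,
    )
    paths = export_cohort(outdir, model, tracks, records, truth, methylome)
    manifest["stages"].append(
        {
            "stage": "simulate",
            "n_sv_records": len(records),
            "n_events": len(events),
            "n_methylation_sites": int(len(methylome)),
        }
    )

    # ----------------------------------------------------------- filter-sv
    fparams = FilterParams(**config.get("filter", {}))
    kept, report = filter_cascade(records, model.cohort, fparams)
    divergent = divergent_among_f1(kept, model.cohort)
    pd.DataFrame(
        report.stage_counts, columns=["stage", "records_in", "records_out"]
    ).to_csv(os.path.join(outdir, "filter_report.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "id": d.record.id,
                "chrom": d.record.chrom,
                "pos": d.record.pos,
                "sv_type": d.record.sv_type,
                "majority": d.majority_class.name,
                "deviants": ",".join(d.deviant_samples),
            }
            for d in divergent
        ]
    ).to_csv(os.path.join(outdir, "divergent_sv.tsv"), sep="\t", index=False)
    manifest["stages"].append(
        {
            "stage": "filter-sv",
            "records_in": report.n_in,
            "records_out": report.n_out,
            "divergent": len(divergent),
        }
    )

    # ------------------------------------------------- detect-rearrangements
    dparams = scaled_detection_params(scale, **config.get("detect", {}))
    centromeres = {}
    for chrom in model.cohort.chrom_lengths:
        est = estimate_centromere(
            model.repeats.get(chrom, []), model.breakpoints.get(chrom, [])
        )
        if est is not None:
            centromeres[chrom] = est
    f1_tracks = {s: tracks[s] for s in model.cohort.f1_samples}
    calls, reject_log = detect_rearrangements(
        f1_tracks, divergent, model.cohort, dparams, centromeres
    )
    manifest["stages"].append(
        {"stage": "detect-rearrangements", "calls": len(calls),
         "rejected_candidates": len(reject_log)}
    )

    # ------------------------------------------------------------ detect-hne
    hparams = HneParams(**config.get("hne", {}))
    pairs = select_pairs(model.pairs, hparams)
    del_segments, dup_segments = [], []
    for sample in model.cohort.f1_samples:
        for chrom, track in tracks[sample].items():
            for seg in call_depth_segments(track, hparams):
                (del_segments if seg.seg_type == "DEL" else dup_segments).append(seg)
    nrhe_calls = match_nrhe(
        del_segments, dup_segments, pairs, model.genes, model.partners, hparams
    )
    refine_nrhe_calls(nrhe_calls, tracks, hparams)
    linked = classify_rearrangements(calls, nrhe_calls)
    rows = []
    for call, nrhe in linked:
        rows.append(
            {
                "sample": call.sample,
                "chrom": call.interval.chrom,
                "start": call.interval.start,
                "end": call.interval.end,
                "length": call.interval.length,
                "segment_cov": round(call.segment_cov, 2),
                "chrom_cov": round(call.chrom_cov, 2),
                "n_hom_ref": call.n_hom_ref,
                "n_het": call.n_het,
                "n_hom_alt": call.n_hom_alt,
                "location": call.location_class,
                "type": call.event_type,
                "dup_chrom": nrhe.refined_dup.chrom if nrhe else "",
                "dup_start": nrhe.refined_dup.start if nrhe else "",
                "dup_end": nrhe.refined_dup.end if nrhe else "",
                "n_pairs": len(nrhe.supporting_pairs) if nrhe else 0,
            }
        )
    events_df = pd.DataFrame(rows)
    events_df.to_csv(os.path.join(outdir, "rearrangements.tsv"), sep="\t", index=False)
    manifest["stages"].append(
        {
            "stage": "detect-hne",
            "selected_pairs": len(pairs),
            "del_segments": len(del_segments),
            "dup_segments": len(dup_segments),
            "nrhe_calls": len(nrhe_calls),
            "linked_nrhe": sum(1 for _, n in linked if n is not None),
        }
    )

    # ------------------------------------------------------------- call-dmrs
    mparams = DmrParams(**config.get("dmr", {}))
    control_sites = methylome[methylome["sample"] == control]
    control_bins = aggregate_bins(control_sites, mparams.bin_size, context)
    repeat_ivs = [iv for ivs in model.repeats.values() for iv in ivs]
    all_dmrs = []
    for sample in meth_samples:
        sample_sites = methylome[methylome["sample"] == sample]
        if not len(sample_sites):
            continue
        dmrs = call_dmrs(
            aggregate_bins(sample_sites, mparams.bin_size, context),
            control_bins,
            mparams,
            context=context,
        )
        if len(dmrs):
            dmrs = annotate_dmrs(
                dmrs, model.all_genes, repeat_ivs, model.cohort.chrom_lengths
            )
            dmrs.insert(0, "sample", sample)
            all_dmrs.append(dmrs)
    dmr_df = (
        pd.concat(all_dmrs, ignore_index=True)
        if all_dmrs
        else pd.DataFrame(columns=["sample", "chrom", "start", "end"])
    )
    dmr_df.to_csv(os.path.join(outdir, "dmrs.tsv"), sep="\t", index=False)
    manifest["stages"].append({"stage": "call-dmrs", "dmrs": int(len(dmr_df))})

    # -------------------------------------------------------------- annotate
    deletions = [(c.sample, c.interval) for c, _ in linked]
    duplications = [
        (n.sample, n.refined_dup) for _, n in linked if n is not None
    ]
    tally = tally_gene_cnv(deletions, duplications, model.all_genes)
    pd.DataFrame(
        [
            {k: v for k, v in event.items() if k != "genes"}
            for event in tally.per_event
        ]
    ).to_csv(os.path.join(outdir, "gene_cnv.tsv"), sep="\t", index=False)
    ortho = None
    if config.get("hits_tsv"):
        hits = pd.read_csv(config["hits_tsv"], sep="\t")
        ortho = filter_ortholog_hits(hits)
        ortho.to_csv(os.path.join(outdir, "ortholog_hits.tsv"), sep="\t", index=False)
    manifest["stages"].append(
        {
            "stage": "annotate",
            "genes_deleted": tally.total_deleted,
            "genes_duplicated": tally.total_duplicated,
            "ortholog_assignments": None if ortho is None else int(len(ortho)),
        }
    )

    manifest["artifacts"] = {
        key: os.path.relpath(path, outdir) for key, path in paths.items()
    }
    manifest["params"] = {
        "sim": dataclasses.asdict(sim_cfg),
        "filter": dataclasses.asdict(fparams),
        "detect": dataclasses.asdict(dparams),
        "hne": dataclasses.asdict(hparams),
        "dmr": dataclasses.asdict(mparams),
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
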