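import pytest

from homeox import reference
from homeox.models import AlleleClass, CohortModel, GenotypeCall, SVRecord
from homeox.pipeline import scaled_detection_params
from homeox.simulate import SimConfig, build_genome_model, simulate_cohort
from homeox.svfilter import divergent_among_f1, filter_cascade


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def genome_model(sim_config):
    return build_genome_model(sim_config)


@pytest.fixture(scope="session")
def cohort(genome_model):
    return genome_model.cohort


@pytest.fixture(scope="session")
def reference_events():
    return reference.reference_events()


@pytest.fixture(scope="session")
def seeded_cohort_run(genome_model, reference_events, sim_config):
    """One fully simulated cohort (seed 1) with the five planted reference
    rearrangements, shared by the detection-level tests."""
    tracks, records, truth = simulate_cohort(
        genome_model, reference_events, sim_config
    )
    kept, report = filter_cascade(records, genome_model.cohort)
    divergent = divergent_among_f1(kept, genome_model.cohort)
    return {
        "model": genome_model,
        "tracks": tracks,
        "records": records,
        "truth": truth,
        "kept": kept,
        "report": report,
        "divergent": divergent,
        "params": scaled_detection_params(),
    }


def make_uniform_record(
    cohort: CohortModel,
    record_id: str = "r1",
    chrom: str | None = None,
    f1_overrides: dict[str, GenotypeCall] | None = None,
    **kwargs,
) -> SVRecord:
    """A clean DEL record: paternal HOM_ALT, maternal HOM_REF, F1s HET."""
    calls = {
        cohort.maternal: GenotypeCall(AlleleClass.HOM_REF, 29, 1),
        cohort.paternal: GenotypeCall(AlleleClass.HOM_ALT, 1, 29),
    }
    calls.update({s: GenotypeCall(AlleleClass.HET, 15, 15) for s in cohort.f1_samples})
    calls.update(f1_overrides or {})
    fields = dict(
        id=record_id,
        chrom=chrom or next(iter(cohort.chrom_lengths)),
        pos=1000,
        sv_type="DEL",
        sv_length=500,
        precise=True,
        calls=calls,
    )
    fields.update(kwargs)
    return SVRecord(**fields)
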