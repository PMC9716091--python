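import numpy as np
import pytest

from _oracles import window_counts_bruteforce
from conftest import make_uniform_record
from homeox.errors import ConfigError, RefinementError
from homeox.models import (
    AlleleClass,
    CoverageTrack,
    GenomicInterval,
    GenotypeCall,
)
from homeox.rearrangements import (
    CentromereEstimate,
    DetectionParams,
    build_window_profiles,
    classify_location,
    detect_candidate_regions,
    detect_rearrangements,
    estimate_centromere,
    refine_boundaries,
)
from homeox.svfilter import DivergentCall


def _divergent(cohort, chrom, pos, sample_class):
    overrides = {
        s: GenotypeCall(cls, 15, 15) for s, cls in sample_class.items()
    }
    rec = make_uniform_record(
        cohort, record_id=f"d_{chrom}_{pos}", chrom=chrom, pos=pos,
        f1_overrides=overrides,
    )
    deviants = list(sample_class)
    return DivergentCall(rec, AlleleClass.HET, deviants)


class TestWindowProfiles:
    def test_window_counts_and_means(self, cohort):
        chrom = "A01"
        track = CoverageTrack("F1_01", chrom, 10_000, 1_000_000,
                              np.full(100, 40.0))
        divergent = [
            _divergent(cohort, chrom, 200_000,
                       {"F1_01": AlleleClass.HET}),
            _divergent(cohort, chrom, 800_000,
                       {"F1_01": AlleleClass.HET}),
        ]
        profiles = build_window_profiles({chrom: track}, divergent,
                                         window=1_000_000)
        profile = profiles["F1_01"][chrom]
        assert profile.n_het.tolist() == [2]
        assert profile.n_hom_ref.tolist() == [0]
        assert profile.mean_depth[0] == pytest.approx(40.0)

    def test_window_must_be_multiple_of_bin(self, cohort):
        track = CoverageTrack("F1_01", "A01", 30_000, 900_000, np.full(30, 40.0))
        with pytest.raises(ConfigError):
            build_window_profiles({"A01": track}, [], window=1_000_000)

    def test_counts_match_bruteforce_recount(self, cohort):
        rng = np.random.default_rng(2)
        chrom, length, window = "A01", 6_000_000, 250_000
        track = CoverageTrack("F1_01", chrom, 10_000, length,
                              rng.uniform(10, 60, 600))
        classes = rng.choice(
            [AlleleClass.HOM_REF, AlleleClass.HET, AlleleClass.HOM_ALT], 80
        )
        positions = sorted(int(p) for p in rng.integers(1, length + 1, 80))
        divergent = [
            _divergent(cohort, chrom, pos, {"F1_01": cls})
            for pos, cls in zip(positions, classes)
        ]
        profile = build_window_profiles({chrom: track}, divergent,
                                        window=window)["F1_01"][chrom]
        expected = window_counts_bruteforce(
            positions, [c.name for c in classes], window, len(profile.intervals)
        )
        assert profile.n_hom_ref.tolist() == expected["HOM_REF"]
        assert profile.n_het.tolist() == expected["HET"]
        assert profile.n_hom_alt.tolist() == expected["HOM_ALT"]


class TestCandidateRegions:
    def _profile(self, cohort, het, hom_ref, depth, window=250_000):
        chrom = "A01"
        n = len(het)
        track = CoverageTrack(
            "F1_01", chrom, 10_000, n * window,
            np.repeat(depth, window // 10_000),
        )
        profiles = build_window_profiles({chrom: track}, [], window=window)
        profile = profiles["F1_01"][chrom]
        profile.n_het = np.array(het)
        profile.n_hom_ref = np.array(hom_ref)
        return profile

    def test_uniform_het_profile_yields_nothing(self, cohort):
        profile = self._profile(cohort, [2, 3, 1, 2], [0, 0, 0, 0],
                                np.full(4, 40.0))
        assert detect_candidate_regions(profile, 40.0) == []

    def test_three_qualifying_windows_form_one_candidate(self, cohort):
        profile = self._profile(
            cohort, [1, 0, 0, 0, 1], [0, 2, 3, 2, 0],
            np.array([40.0, 20.0, 20.0, 20.0, 40.0]),
        )
        [cand] = detect_candidate_regions(profile, 40.0)
        assert (cand.start, cand.end) == (250_000, 1_000_000)

    def test_low_coverage_without_informative_sv_disqualified(self, cohort):
        profile = self._profile(cohort, [0, 0], [0, 0],
                                np.array([20.0, 20.0]))
        assert detect_candidate_regions(profile, 40.0) == []


class TestRefineBoundaries:
    def test_step_function_boundary_within_one_bin(self):
        depths = np.full(500, 40.0)
        depths[200:320] = 20.0
        track = CoverageTrack("s", "A01", 10_000, 5_000_000, depths)
        refined = refine_boundaries(
            track, GenomicInterval("A01", 2_100_000, 3_000_000), 40.0
        )
        assert abs(refined.start - 2_000_000) <= 10_000
        assert abs(refined.end - 3_200_000) <= 10_000

    def test_constant_track_raises_refinement_error(self):
        track = CoverageTrack("s", "A01", 10_000, 3_000_000, np.full(300, 40.0))
        with pytest.raises(RefinementError):
            refine_boundaries(
                track, GenomicInterval("A01", 1_000_000, 2_000_000), 40.0
            )

    def test_refinement_is_idempotent(self):
        rng = np.random.default_rng(8)
        depths = rng.normal(40, 6, 500).clip(1)
        depths[150:280] = rng.normal(20, 4.5, 130).clip(1)
        track = CoverageTrack("s", "A01", 10_000, 5_000_000, depths)
        first = refine_boundaries(
            track, GenomicInterval("A01", 1_500_000, 2_800_000), 40.0
        )
        second = refine_boundaries(track, first, 40.0)
        assert first == second

    def test_coarse_bins_rejected(self):
        track = CoverageTrack("s", "A01", 50_000, 5_000_000, np.full(100, 40.0))
        with pytest.raises(ConfigError):
            refine_boundaries(
                track, GenomicInterval("A01", 0, 1_000_000), 40.0
            )


class TestCentromereEstimate:
    def test_cluster_flanked_by_breakpoints(self):
        hits = [
            GenomicInterval("C01", p, p + 500)
            for p in range(10_000_000, 11_000_000, 50_000)
        ]
        est = estimate_centromere(hits, [9_800_000, 11_300_000])
        assert est.interval == GenomicInterval("C01", 9_800_000, 11_300_000)

    def test_larger_second_cluster_wins(self):
        first = [GenomicInterval("C01", p, p + 500) for p in (0, 100_000)]
        second = [
            GenomicInterval("C01", p, p + 500)
            for p in range(5_000_000, 5_400_000, 100_000)
        ]
        est = estimate_centromere(first + second, [])
        assert est.interval.start == 5_000_000

    def test_no_hits_returns_none(self):
        assert estimate_centromere([], [1000]) is None

    def test_simulated_centromeres_recovered(self):
        """The estimate contains the planted satellite array for every
        chromosome across 20 seeds."""
        from homeox.simulate import SimConfig, build_genome_model

        for seed in range(20):
            model = build_genome_model(SimConfig(seed=seed))
            for chrom, truth in model.centromere_truth.items():
                est = estimate_centromere(
                    model.repeats[chrom], model.breakpoints[chrom]
                )
                assert est is not None
                assert est.interval.start <= truth.start
                assert est.interval.end >= truth.end


class TestClassifyLocation:
    params = DetectionParams(pericen_dist=2_000_000)
    centromere = CentromereEstimate(
        "C01", GenomicInterval("C01", 29_000_000, 31_000_000)
    )

    def test_interval_touching_chromosome_start_is_telomeric(self):
        iv = GenomicInterval("C01", 0, 2_000_000)
        assert classify_location(iv, self.centromere, 60_000_000, self.params) == (
            "telomeric"
        )

    def test_interval_abutting_centromere_is_pericentromeric(self):
        iv = GenomicInterval("C01", 27_000_000, 29_000_000)
        assert classify_location(iv, self.centromere, 60_000_000, self.params) == (
            "pericentromeric"
        )

    def test_mid_arm_interval_is_interstitial(self):
        iv = GenomicInterval("C01", 14_000_000, 16_000_000)
        assert classify_location(iv, self.centromere, 60_000_000, self.params) == (
            "interstitial"
        )


class TestDetectRearrangements:
    def test_reference_events_recovered_with_correct_carriers(
        self, seeded_cohort_run
    ):
        """The five planted reference rearrangements (seven carrier calls,
        C01 shared by three siblings) are all recovered at seed 1."""
        run = seeded_cohort_run
        calls, log = detect_rearrangements(
            {s: run["tracks"][s] for s in run["model"].cohort.f1_samples},
            run["divergent"],
            run["model"].cohort,
            run["params"],
        )
        expected = {
            (ev["del"][0], ev["carrier"]) for ev in run["truth"]["events"]
        }
        assert {(c.interval.chrom, c.sample) for c in calls} == expected
        assert len(calls) == 7
        for call in calls:
            assert call.interval.length > run["params"].min_event_len
            assert call.n_het == 0 and call.n_hom_ref >= 1
            assert call.coverage_ratio < 0.65

    def test_locations_match_reference_geometry(self, seeded_cohort_run):
        """A09/A10/C03/C08 events lie telomerically, the C01 event
        pericentromerically."""
        run = seeded_cohort_run
        model = run["model"]
        centromeres = {
            chrom: estimate_centromere(model.repeats[chrom],
                                       model.breakpoints[chrom])
            for chrom in model.cohort.chrom_lengths
        }
        calls, _ = detect_rearrangements(
            {s: run["tracks"][s] for s in model.cohort.f1_samples},
            run["divergent"], model.cohort, run["params"], centromeres,
        )
        by_chrom = {}
        for call in calls:
            by_chrom.setdefault(call.interval.chrom, set()).add(
                call.location_class
            )
        assert by_chrom["C01"] == {"pericentromeric"}
        for chrom in ("A09", "A10", "C03", "C08"):
            assert by_chrom[chrom] == {"telomeric"}
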