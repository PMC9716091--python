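import numpy as np
import pandas as pd
import pytest

from _oracles import depth_segments_bruteforce
from homeox.hne import (
    HneParams,
    call_depth_segments,
    classify_rearrangements,
    match_nrhe,
    refine_duplication_extent,
    refine_nrhe_calls,
    select_pairs,
)
from homeox.models import CoverageTrack, GenomicInterval
from homeox.rearrangements import detect_rearrangements
from homeox.svfilter import divergent_among_f1, filter_cascade


def _pairs_df(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_c", "similarity"])


class TestSelectPairs:
    def test_highest_similarity_partner_wins(self):
        pairs = select_pairs(_pairs_df([("A1", "C1", 80), ("A1", "C2", 75)]))
        assert [(p.gene_a, p.gene_c) for p in pairs] == [("A1", "C1")]

    def test_similarity_tie_broken_by_input_order(self):
        pairs = select_pairs(_pairs_df([("A1", "C1", 80), ("A1", "C2", 80)]))
        assert [(p.gene_a, p.gene_c) for p in pairs] == [("A1", "C1")]

    def test_below_threshold_candidates_dropped(self):
        assert select_pairs(_pairs_df([("A1", "C1", 65), ("A2", "C2", 69.9)])) == []

    def test_each_gene_in_at_most_one_pair(self):
        pairs = select_pairs(
            _pairs_df(
                [("A1", "C1", 95), ("A2", "C1", 99), ("A2", "C2", 80),
                 ("A3", "C3", 71)]
            )
        )
        genes = [g for p in pairs for g in (p.gene_a, p.gene_c)]
        assert len(genes) == len(set(genes))
        assert ("A2", "C1") in [(p.gene_a, p.gene_c) for p in pairs]


class TestCallDepthSegments:
    def test_constant_track_has_no_segments(self):
        track = CoverageTrack("s", "A01", 10_000, 1_000_000, np.full(100, 40.0))
        assert call_depth_segments(track) == []

    def test_thirty_low_bins_form_one_deletion_segment(self):
        rng = np.random.default_rng(0)
        depths = rng.normal(40, 4, 300).clip(25, 55)
        depths[100:130] = 20.0
        track = CoverageTrack("s", "A01", 1000, 300_000, depths)
        segments = call_depth_segments(track, HneParams(min_seg_len=25_000))
        dels = [s for s in segments if s.seg_type == "DEL"]
        assert len(dels) == 1
        assert dels[0].interval == GenomicInterval("A01", 100_000, 130_000)
        assert dels[0].mean_depth == pytest.approx(20.0)

    def test_equals_bruteforce_oracle_on_random_tracks(self):
        """SD-threshold labelling + merge agrees with direct enumeration on
        500 random negative-binomial tracks with outliers."""
        rng = np.random.default_rng(42)
        params = HneParams(min_seg_len=30_000)
        for _ in range(500):
            n = int(rng.integers(10, 200))
            depths = rng.negative_binomial(40, 0.5, n).astype(float)
            outliers = rng.random(n) < 0.03
            depths[outliers] = rng.uniform(151, 400, outliers.sum())
            track = CoverageTrack("s", "A01", 10_000, n * 10_000, depths)
            got = [
                (seg.interval.start // 10_000, seg.interval.end // 10_000,
                 seg.seg_type)
                for seg in call_depth_segments(track, params)
            ]
            expected = depth_segments_bruteforce(
                depths.tolist(), 10_000, params.min_seg_len, params.outlier_cap
            )
            assert got == expected

    def test_bin_size_must_not_exceed_segment_floor(self):
        track = CoverageTrack("s", "A01", 50_000, 1_000_000, np.full(20, 40.0))
        with pytest.raises(Exception):
            call_depth_segments(track, HneParams(min_seg_len=25_000))


class TestRefineDuplicationExtent:
    def _track(self, values, bin_size=100_000):
        return CoverageTrack(
            "s", "A01", bin_size, len(values) * bin_size, np.array(values)
        )

    def test_sixty_x_bins_satisfy_both_conditions(self):
        rng = np.random.default_rng(1)
        depths = rng.normal(40, 4, 100).clip(28, 52)
        depths[40:50] = 60.0
        track = self._track(depths)
        from homeox.hne import DepthSegment

        seg = DepthSegment("s", "A01", GenomicInterval("A01", 4_100_000, 4_800_000),
                           "DUP", 60.0)
        refined = refine_duplication_extent(track, seg)
        assert refined == GenomicInterval("A01", 4_000_000, 5_000_000)

    def test_48x_fails_fold_condition_despite_sd(self):
        """48 < 1.25 x 40: the fold and SD conditions are conjunctive."""
        rng = np.random.default_rng(1)
        depths = rng.normal(40, 4, 100).clip(28, 52)
        depths[40:50] = 48.0
        mu = depths.mean()
        assert 48 >= mu + depths.std()  # SD condition alone would pass
        track = self._track(depths)
        from homeox.hne import DepthSegment

        seg = DepthSegment("s", "A01", GenomicInterval("A01", 4_000_000, 5_000_000),
                           "DUP", 48.0)
        refined = refine_duplication_extent(track, seg)
        assert refined == seg.interval  # fallback: nothing qualified


class TestMatchAndClassify:
    def test_nrhe_reciprocity_on_seeded_cohort(self, seeded_cohort_run):
        """Planted NRHEs produce exactly one linked exchange per event and
        plain deletions stay unlinked, with dup partners on the correct
        homoeologous chromosomes."""
        run = seeded_cohort_run
        model = run["model"]
        params = HneParams()
        pairs = select_pairs(model.pairs, params)
        del_segments, dup_segments = [], []
        for sample in model.cohort.f1_samples:
            for track in run["tracks"][sample].values():
                for seg in call_depth_segments(track, params):
                    (del_segments if seg.seg_type == "DEL" else dup_segments
                     ).append(seg)
        nrhe = match_nrhe(
            del_segments, dup_segments, pairs, model.genes, model.partners,
            params,
        )
        refine_nrhe_calls(nrhe, run["tracks"], params)
        calls, _ = detect_rearrangements(
            {s: run["tracks"][s] for s in model.cohort.f1_samples},
            run["divergent"], model.cohort, run["params"],
        )
        linked = classify_rearrangements(calls, nrhe)
        got = {
            (c.sample, c.interval.chrom, c.event_type,
             n.dup_segment.chrom if n else None)
            for c, n in linked
        }
        assert got == {
            ("F1_06", "A09", "NRHE", "C08"),
            ("F1_05", "A10", "NRHE", "C09"),
            ("F1_01", "C08", "NRHE", "A09"),
            ("F1_02", "C01", "SEG_DEL", None),
            ("F1_03", "C01", "SEG_DEL", None),
            ("F1_04", "C01", "SEG_DEL", None),
            ("F1_02", "C03", "SEG_DEL", None),
        }
        for _, n in linked:
            if n is not None:
                assert n.supporting_pairs
                assert n.del_segment.chrom[0] != n.dup_segment.chrom[0]

    def test_refined_dup_extent_matches_truth_within_one_bin(
        self, seeded_cohort_run
    ):
        run = seeded_cohort_run
        model = run["model"]
        params = HneParams()
        truth_events = [
            (ev["carrier"], GenomicInterval(*ev["del"]),
             GenomicInterval(*ev["dup"]))
            for ev in run["truth"]["events"]
            if ev["dup"] is not None
        ]
        pairs = select_pairs(model.pairs, params)
        del_segments, dup_segments = [], []
        for sample in model.cohort.f1_samples:
            for track in run["tracks"][sample].values():
                for seg in call_depth_segments(track, params):
                    (del_segments if seg.seg_type == "DEL" else dup_segments
                     ).append(seg)
        nrhe = match_nrhe(
            del_segments, dup_segments, pairs, model.genes, model.partners,
            params,
        )
        for carrier, del_iv, dup_iv in truth_events:
            matching = [
                c for c in nrhe
                if c.sample == carrier and c.del_segment.interval.overlaps(del_iv)
            ]
            assert matching, (carrier, del_iv)
            best = max(matching, key=lambda c: len(c.supporting_pairs))
            refined = refine_duplication_extent(
                run["tracks"][carrier][best.dup_segment.chrom],
                best.dup_segment, params,
            )
            assert refined.chrom == dup_iv.chrom
            assert abs(refined.start - dup_iv.start) <= params.dup_bin_size
            assert abs(refined.end - dup_iv.end) <= params.dup_bin_size

    def test_dup_without_deletion_ignored(self, genome_model):
        from homeox.hne import DepthSegment

        dup = DepthSegment("F1_01", "C08",
                           GenomicInterval("C08", 0, 100_000), "DUP", 60.0)
        pairs = select_pairs(genome_model.pairs)
        assert match_nrhe([], [dup], pairs, genome_model.genes,
                          genome_model.partners) == []
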