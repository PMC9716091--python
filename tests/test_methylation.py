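import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from _oracles import nearest_gene_bruteforce
from homeox.errors import AlignmentError, UndefinedTestError
from homeox.methylation import (
    DmrParams,
    aggregate_bins,
    annotate_dmrs,
    call_dmrs,
    count_methylated_cytosines,
    score_test,
)
from homeox.models import GeneModel, GenomicInterval


def _sites(rows, sample="F1_01", chrom="A01", context="CpG"):
    df = pd.DataFrame(rows, columns=["pos", "n_meth", "n_total"])
    df.insert(0, "sample", sample)
    df.insert(1, "chrom", chrom)
    df["strand"] = "+"
    df["context"] = context
    df["frequency"] = np.where(df.n_total > 0, df.n_meth / df.n_total, 0.0)
    return df[
        ["sample", "chrom", "pos", "strand", "context", "n_meth", "n_total",
         "frequency"]
    ]


class TestAggregateBins:
    def test_two_sites_in_one_bin(self):
        bins = aggregate_bins(_sites([(100, 5, 10), (900, 15, 20)]), 1000)
        assert len(bins) == 1
        row = bins.iloc[0]
        assert (row.n_cytosines, row.n_meth, row.n_total) == (2, 20, 30)
        assert row.proportion == pytest.approx(20 / 30)

    def test_empty_bins_on_full_grid(self):
        bins = aggregate_bins(
            _sites([(100, 5, 10)]), 1000, chrom_lengths={"A01": 3000}
        )
        assert len(bins) == 3
        empty = bins.iloc[1]
        assert (empty.n_cytosines, empty.n_meth, empty.n_total) == (0, 0, 0)
        assert np.isnan(empty.proportion)

    def test_matches_bruteforce_accumulation(self):
        rng = np.random.default_rng(4)
        n = 500
        pos = rng.integers(0, 50_000, n)
        n_total = rng.integers(1, 60, n)
        n_meth = rng.binomial(n_total, 0.3)
        sites = _sites(list(zip(pos, n_meth, n_total)))
        bins = aggregate_bins(sites, 1000)
        expected = {}
        for p, m, t in zip(pos, n_meth, n_total):
            b = p // 1000
            cc, sm, st = expected.get(b, (0, 0, 0))
            expected[b] = (cc + 1, sm + m, st + t)
        for row in bins.itertuples(index=False):
            assert expected[row.start // 1000] == (
                row.n_cytosines, row.n_meth, row.n_total
            )
        assert len(bins) == len(expected)


class TestCountMethylatedCytosines:
    def test_threshold_and_coverage_rules(self):
        sites = _sites([(1, 9, 10), (2, 4, 10), (3, 6, 10)])
        assert count_methylated_cytosines(sites) == 2
        low_cov = _sites([(1, 3, 3)])
        assert count_methylated_cytosines(low_cov, min_site_cov=4) == 0

    def test_all_unmethylated(self):
        assert count_methylated_cytosines(_sites([(1, 0, 10), (2, 0, 8)])) == 0


class TestScoreTest:
    def test_equal_proportions_give_null(self):
        z, p = score_test(20, 40, 10, 20)
        assert z == 0 and p == 1

    def test_worked_example_z_six(self):
        """(40/50) vs (10/50): pooled 0.5, SE 0.1, z = 6."""
        z, p = score_test(40, 50, 10, 50)
        assert z == pytest.approx(6.0)

    def test_degenerate_pooled_proportion(self):
        assert score_test(0, 50, 0, 50) == (0.0, 1.0)
        assert score_test(50, 50, 50, 50) == (0.0, 1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(UndefinedTestError):
            score_test(0, 0, 5, 10)

    def test_z_squared_equals_pearson_chi_square(self):
        """z^2 reproduces the 2x2 Pearson statistic without continuity
        correction to 1e-9 on 1000 random tables."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 1000:
            n1, n2 = rng.integers(2, 500, 2)
            m1 = rng.integers(0, n1 + 1)
            m2 = rng.integers(0, n2 + 1)
            if (m1 + m2) in (0, n1 + n2):
                continue  # degenerate margin: chi-square undefined
            z, _ = score_test(m1, n1, m2, n2)
            chi2 = chi2_contingency(
                [[m1, n1 - m1], [m2, n2 - m2]], correction=False
            ).statistic
            assert z**2 == pytest.approx(chi2, abs=1e-9)
            checked += 1


class TestCallDmrs:
    def _bins(self, spec):
        """spec: list of (start, cc, m, t)."""
        df = pd.DataFrame(spec, columns=["start", "n_cytosines", "n_meth",
                                         "n_total"])
        df["chrom"] = "A01"
        df["end"] = df["start"] + 1000
        df["proportion"] = df.n_meth / df.n_total
        return df

    def test_large_difference_small_p_required_jointly(self):
        """A 0.3 proportion difference is rejected regardless of p-value."""
        f1 = self._bins([(0, 10, 200, 400)])
        ctrl = self._bins([(0, 10, 320, 400)])  # diff 0.3, p tiny
        assert len(call_dmrs(f1, ctrl, DmrParams())) == 0

    def test_min_cytosine_count_enforced(self):
        f1 = self._bins([(0, 3, 0, 120)])
        ctrl = self._bins([(0, 10, 110, 120)])
        assert len(call_dmrs(f1, ctrl, DmrParams())) == 0

    def test_abutting_same_direction_bins_merge(self):
        f1 = self._bins([(0, 10, 10, 400), (1000, 10, 12, 400)])
        ctrl = self._bins([(0, 10, 300, 400), (1000, 10, 290, 400)])
        out = call_dmrs(f1, ctrl, DmrParams())
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.start, row.end, row.direction) == (0, 2000, "hypo")
        assert row.n_cytosines_f1 == 20

    def test_opposite_directions_do_not_merge(self):
        f1 = self._bins([(0, 10, 10, 400), (1000, 10, 390, 400)])
        ctrl = self._bins([(0, 10, 300, 400), (1000, 10, 100, 400)])
        out = call_dmrs(f1, ctrl, DmrParams())
        assert list(out.direction) == ["hypo", "hyper"]

    def test_gap_separated_bins_stay_apart_at_zero_gap(self):
        f1 = self._bins([(0, 10, 10, 400), (2000, 10, 12, 400)])
        ctrl = self._bins([(0, 10, 300, 400), (2000, 10, 290, 400)])
        out = call_dmrs(f1, ctrl, DmrParams(min_gap=0))
        assert len(out) == 2

    def test_misaligned_grid_raises(self):
        f1 = self._bins([(0, 10, 10, 400)])
        f1["start"] += 500
        ctrl = self._bins([(0, 10, 300, 400)])
        with pytest.raises(AlignmentError):
            call_dmrs(f1, ctrl, DmrParams())

    def test_planted_hypo_dmr_called_in_20_of_20_seeds(self, genome_model):
        """Delta = 0.5 hypomethylation at 40x with ~10 cytosines per bin is
        always recovered."""
        from homeox.simulate import DmrSpec, SimConfig, simulate_methylome

        region = GenomicInterval("C01", 1_000_000, 1_010_000)
        hits = 0
        for seed in range(20):
            config = SimConfig(
                seed=seed,
                meth_sites_per_kb={"CpG": 10.0, "CHG": 1.0, "CHH": 1.0},
            )
            sites = simulate_methylome(
                genome_model, [], config, chroms=["C01"],
                samples=["F1_01", "G3D001"],
                dmr_regions=[DmrSpec("F1_01", region, "CpG", -0.5)],
            )
            f1 = aggregate_bins(sites[sites["sample"] == "F1_01"], 1000, "CpG")
            ctrl = aggregate_bins(sites[sites["sample"] == "G3D001"], 1000, "CpG")
            out = call_dmrs(f1, ctrl, DmrParams(), context="CpG")
            overlap = out[
                (out.start < region.end) & (out.end > region.start)
                & (out.direction == "hypo")
            ]
            hits += bool(len(overlap))
        assert hits == 20


class TestAnnotateDmrs:
    genes = [
        GeneModel(
            "g1", GenomicInterval("A01", 10_000, 14_000), "+",
            exons=[
                GenomicInterval("A01", 10_000, 11_000),
                GenomicInterval("A01", 13_000, 14_000),
            ],
        ),
        GeneModel("g2", GenomicInterval("A01", 50_000, 52_000), "-"),
    ]
    repeats = [GenomicInterval("A01", 30_000, 31_000)]
    lengths = {"A01": 100_000}

    def _dmrs(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def test_dmr_inside_exon(self):
        out = annotate_dmrs(
            self._dmrs([("A01", 10_200, 10_800)]), self.genes, self.repeats,
            self.lengths,
        )
        row = out.iloc[0]
        assert row.in_exon and not row.in_repeat and row.nearest_gene_bp == 0

    def test_dmr_in_intron_not_exon(self):
        out = annotate_dmrs(
            self._dmrs([("A01", 11_200, 12_800)]), self.genes, self.repeats,
            self.lengths,
        )
        row = out.iloc[0]
        assert row.in_intron and not row.in_exon

    def test_promoter_convention_plus_and_minus(self):
        plus = annotate_dmrs(
            self._dmrs([("A01", 9_400, 9_600)]), self.genes, self.repeats,
            self.lengths,
        ).iloc[0]
        assert plus.in_promoter  # 500 bp upstream of + strand gene start
        minus = annotate_dmrs(
            self._dmrs([("A01", 52_300, 52_600)]), self.genes, self.repeats,
            self.lengths,
        ).iloc[0]
        assert minus.in_promoter  # downstream in coordinates = upstream of -

    def test_nearest_distance_matches_bruteforce(self):
        rng = np.random.default_rng(9)
        bounds = [(g.interval.start, g.interval.end) for g in self.genes]
        rows = []
        for _ in range(50):
            start = int(rng.integers(0, 99_000))
            rows.append(("A01", start, start + 500))
        out = annotate_dmrs(
            self._dmrs(rows), self.genes, self.repeats, self.lengths
        )
        for (_, start, end), got in zip(rows, out.nearest_gene_bp):
            assert got == nearest_gene_bruteforce(start, end, bounds)
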