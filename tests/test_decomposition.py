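import numpy as np
import pandas as pd
import pytest

from svsnv.decomposition import (WindowCountTable, chromosome_sv_stats,
                                 compare_conditions, count_in_windows,
                                 fit_decomposition)
from svsnv.genome import GenomeDef
from svsnv.synthetic_data import simulate_svs
from svsnv.variant_io import SnvRecord, SvBreakend


def make_table(pairs, w=1_000_000):
    """WindowCountTable from (sv, snv) count pairs; all full windows."""
    rows = [["chr1", i * w + 1, (i + 1) * w, w, False, sv, snv]
            for i, (sv, snv) in enumerate(pairs)]
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                     "partial", "sv_count", "snv_count"])
    return WindowCountTable(w, df)


class TestCountInWindows:
    def test_two_windows_one_snv_each(self):
        g = GenomeDef.from_lengths({"chr1": 100})
        snvs = [SnvRecord("chr1", 10, "C", "A"), SnvRecord("chr1", 60, "C", "A")]
        tab = count_in_windows(snvs, [], g, w=50).table
        assert tab["snv_count"].tolist() == [1, 1]
        assert tab["start"].tolist() == [1, 51]
        assert tab["end"].tolist() == [50, 100]

    def test_no_events_window_count(self):
        g = GenomeDef.from_lengths({"chr1": 105, "chr2": 50})
        tab = count_in_windows([], [], g, w=50).table
        assert len(tab) == 3 + 1  # ceil(105/50) + ceil(50/50)
        assert tab["sv_count"].sum() == 0 and tab["snv_count"].sum() == 0
        assert tab["partial"].tolist() == [False, False, True, False]

    def test_matches_integer_division_oracle(self, rng):
        g = GenomeDef.from_lengths({"chr1": 10_000, "chr2": 7_500})
        w = 1000
        snvs = [SnvRecord(c, int(p), "C", "A")
                for c in g.names
                for p in rng.integers(1, g.lengths[c] + 1, size=200)]
        bes = [SvBreakend(c, int(p), "DEL", f"e{i}")
               for c in g.names
               for i, p in enumerate(rng.integers(1, g.lengths[c] + 1, size=30))]
        tab = count_in_windows(snvs, bes, g, w=w).table
        for _, row in tab.iterrows():
            n_snv = sum(1 for s in snvs if s.chrom == row.chrom
                        and (s.pos - 1) // w == (row.start - 1) // w)
            n_sv = sum(1 for b in bes if b.chrom == row.chrom
                       and (b.pos - 1) // w == (row.start - 1) // w)
            assert (row.snv_count, row.sv_count) == (n_snv, n_sv)
        assert tab["snv_count"].sum() == len(snvs)  # conservation


class TestFitDecomposition:
    def test_exact_line(self):
        res = fit_decomposition(make_table([(0, 10), (1, 15), (2, 20)]))
        assert res.slope == pytest.approx(5.0)
        assert res.intercept == pytest.approx(10.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.intercept_rate == pytest.approx(10.0)  # per 1 Mb window

    def test_constant_snv_counts_zero_slope(self):
        res = fit_decomposition(make_table([(0, 7), (1, 7), (3, 7), (5, 7)]))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(7.0)

    def test_degenerate_design_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_decomposition(make_table([(2, 1), (2, 5), (2, 9)]))

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError, match="3 usable"):
            fit_decomposition(make_table([(0, 1), (1, 2)]))

    def test_noiseless_generator_recovered_to_machine_precision(self):
        """snv = b*(w/1e6) + k*sv per window is recovered exactly."""
        b, k, w = 2.0, 30.0, 15_000_000
        sv = np.arange(12)
        pairs = [(int(s), b * (w / 1e6) + k * s) for s in sv]
        res = fit_decomposition(make_table(pairs, w=w))
        assert res.slope == pytest.approx(k, rel=1e-12)
        assert res.intercept_rate == pytest.approx(b, rel=1e-12)

    def test_partial_windows_dropped_by_default(self):
        rows = [["chr1", 1, 10, 10, False, 0, 5],
                ["chr1", 11, 20, 10, False, 1, 8],
                ["chr1", 21, 30, 10, False, 2, 11],
                ["chr1", 31, 33, 3, True, 9, 0]]
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "length",
                                         "partial", "sv_count", "snv_count"])
        res = fit_decomposition(WindowCountTable(10, df))
        assert res.n_windows == 3
        assert res.slope == pytest.approx(3.0)


class TestCompareConditions:
    def test_identical_results_give_unit_ratios(self):
        res = fit_decomposition(make_table([(0, 10), (1, 16), (2, 19), (3, 27)]))
        comp = compare_conditions(res, res)
        assert comp.slope_ratio.ratio == pytest.approx(1.0)
        assert comp.intercept_rate_ratio.ratio == pytest.approx(1.0)
        assert comp.slope_ratio.ci_low < 1.0 < comp.slope_ratio.ci_high

    def test_zero_intercept_flagged(self):
        res_a = fit_decomposition(make_table([(0, 10), (1, 15), (2, 20)]))
        res_b = fit_decomposition(make_table([(0, 0), (1, 5), (2, 10)]))
        comp = compare_conditions(res_a, res_b)
        assert comp.intercept_rate_ratio.ratio == pytest.approx(0.0, abs=1e-9)
        assert comp.intercept_rate_ratio.ci_low is None  # flagged: no CI

    def test_window_size_mismatch_errors(self):
        res_a = fit_decomposition(make_table([(0, 10), (1, 15), (2, 20)], w=10))
        res_b = fit_decomposition(make_table([(0, 10), (1, 15), (2, 20)], w=20))
        with pytest.raises(ValueError, match="window"):
            compare_conditions(res_a, res_b)


class TestChromosomeSvStats:
    def _genome(self):
        return GenomeDef.from_lengths(
            {"chr1": 2_000_000, "chr2": 1_000_000, "chr3": 1_500_000},
            copy_numbers={"chr1": 2, "chr2": 2, "chr3": 2})

    def _breakends(self, counts):
        out = []
        for chrom, n in counts.items():
            out += [SvBreakend(chrom, 100 + i, "DEL", f"{chrom}_{i}")
                    for i in range(n)]
        return out

    def test_identical_counts_perfect_correlation(self):
        g = self._genome()
        a = self._breakends({"chr1": 5, "chr2": 3, "chr3": 8})
        comp = chromosome_sv_stats(a, list(a), g)
        assert comp.pearson_r == pytest.approx(1.0)

    def test_doubled_counts_correlation_and_normalized_ratio(self):
        g = self._genome()
        a = self._breakends({"chr1": 5, "chr2": 3, "chr3": 8})
        b = self._breakends({"chr1": 10, "chr2": 6, "chr3": 16})
        comp = chromosome_sv_stats(a, b, g)
        assert comp.pearson_r == pytest.approx(1.0)
        assert (comp.normalized_sv_totals["b"]
                == pytest.approx(2 * comp.normalized_sv_totals["a"]))

    def test_shared_hotspots_beat_shuffled_null(self):
        """With shared SV hotspots, the between-condition per-chromosome
        correlation exceeds a hotspot-shuffled null in >=95% of replicates."""
        rng = np.random.default_rng(41)
        lengths = {f"chr{i}": 10_000_000 for i in range(1, 11)}
        g = GenomeDef.from_lengths(lengths)
        hotspots = [(f"chr{i}", 1_000_001, 3_000_000) for i in (1, 4, 7)]
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            a = simulate_svs(g, 60, hotspots, 0.8, rng, "a")
            b = simulate_svs(g, 60, hotspots, 0.8, rng, "b")
            r_obs = chromosome_sv_stats(a, b, g).pearson_r
            # null: same marginal structure, hotspots moved independently
            chroms = list(lengths)
            null_hs_a = [(chroms[i], 1_000_001, 3_000_000)
                         for i in rng.choice(10, size=3, replace=False)]
            null_hs_b = [(chroms[i], 1_000_001, 3_000_000)
                         for i in rng.choice(10, size=3, replace=False)]
            a0 = simulate_svs(g, 60, null_hs_a, 0.8, rng, "a")
            b0 = simulate_svs(g, 60, null_hs_b, 0.8, rng, "b")
            r_null = chromosome_sv_stats(a0, b0, g).pearson_r
            wins += r_obs > r_null
        assert wins >= 0.95 * n_rep
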