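import numpy as np
import pytest

from svsnv.genome import GenomeDef
from svsnv.sv_proximity import (expected_random_count, merge_neighborhoods,
                                observed_vs_expected_curve, partition_snvs)
from svsnv.variant_io import SnvRecord, SvBreakend


def breakend(chrom, pos, i=0):
    return SvBreakend(chrom, pos, "DEL", f"e{i}")


class TestMergeNeighborhoods:
    def test_overlapping_windows_merge(self):
        g = GenomeDef.from_lengths({"chr1": 10_000_000})
        iv = merge_neighborhoods([breakend("chr1", 5_000_000, 0),
                                  breakend("chr1", 5_500_000, 1)],
                                 d=1_000_000, genome=g)
        assert iv.by_chrom["chr1"].tolist() == [[4_000_000, 6_500_000]]

    def test_d_zero_gives_point_intervals(self):
        g = GenomeDef.from_lengths({"chr1": 100})
        iv = merge_neighborhoods([breakend("chr1", 10, 0),
                                  breakend("chr1", 10, 1),
                                  breakend("chr1", 50, 2)], d=0, genome=g)
        assert iv.by_chrom["chr1"].tolist() == [[10, 10], [50, 50]]
        assert iv.total_length() == 2

    def test_clipping_at_chromosome_ends(self):
        g = GenomeDef.from_lengths({"chr1": 100})
        iv = merge_neighborhoods([breakend("chr1", 5)], d=20, genome=g)
        assert iv.by_chrom["chr1"].tolist() == [[1, 25]]

    def test_total_length_matches_per_bp_oracle(self, mb_genome, rng):
        """Merged length equals the brute-force union of per-breakend
        windows, checked base by base on a 1 Mb genome."""
        L = mb_genome.lengths["chr1"]
        for rep in range(5):
            positions = rng.integers(1, L + 1, size=50)
            d = int(rng.integers(0, 30_000))
            bes = [breakend("chr1", int(p), i) for i, p in enumerate(positions)]
            iv = merge_neighborhoods(bes, d, mb_genome)
            member = np.zeros(L + 1, dtype=bool)
            for p in positions:
                member[max(1, p - d): min(L, p + d) + 1] = True
            assert iv.total_length() == int(member.sum())
            # membership agrees at random probe positions too
            probes = rng.integers(1, L + 1, size=500)
            assert np.array_equal(iv.contains("chr1", probes), member[probes])


class TestPartitionSnvs:
    def test_near_and_far_by_distance(self):
        g = GenomeDef.from_lengths({"chr1": 10_000_000})
        snvs = [SnvRecord("chr1", 4_500_000, "C", "A"),
                SnvRecord("chr1", 6_200_000, "C", "A")]
        part = partition_snvs(snvs, [breakend("chr1", 5_000_000)],
                              d=1_000_000, genome=g)
        assert [s.pos for s in part.near] == [4_500_000]
        assert [s.pos for s in part.far] == [6_200_000]

    def test_no_breakends_all_far(self):
        g = GenomeDef.from_lengths({"chr1": 1000})
        snvs = [SnvRecord("chr1", i, "C", "A") for i in (10, 500)]
        part = partition_snvs(snvs, [], d=100, genome=g)
        assert part.near == [] and len(part.far) == 2

    def test_matches_nearest_breakend_brute_force(self, rng):
        g = GenomeDef.from_lengths({"chr1": 200_000, "chr2": 100_000})
        for rep in range(20):
            bes = [breakend(("chr1", "chr2")[int(rng.integers(2))],
                            int(rng.integers(1, 100_001)), i)
                   for i in range(int(rng.integers(1, 20)))]
            snvs = [SnvRecord(("chr1", "chr2")[int(rng.integers(2))],
                              int(rng.integers(1, 100_001)), "C", "T")
                    for _ in range(100)]
            d = int(rng.integers(0, 50_000))
            part = partition_snvs(snvs, bes, d=d, genome=g)
            near_set = {id(s) for s in part.near}
            for s in snvs:
                dist = min((abs(s.pos - b.pos) for b in bes
                            if b.chrom == s.chrom), default=None)
                expected_near = dist is not None and dist <= d
                assert (id(s) in near_set) == expected_near


class TestExpectedRandomCount:
    def test_direct_substitution(self):
        assert expected_random_count(1000, 2_000_000_000, 100, 1_000_000) \
            == pytest.approx(100.0, rel=1e-12)

    def test_zero_svs(self):
        assert expected_random_count(1000, 1_000_000, 0, 1000) == 0.0

    def test_zero_genome_length_errors(self):
        with pytest.raises(ValueError):
            expected_random_count(10, 0, 1, 100)

    def test_uncapped_can_exceed_snv_count(self):
        # the naive formula is implemented verbatim, without capping
        assert expected_random_count(100, 1000, 10, 1000) > 100


class TestObservedVsExpectedCurve:
    def test_zero_snvs_all_zero(self):
        g = GenomeDef.from_lengths({"chr1": 1_000_000})
        curve = observed_vs_expected_curve([], [breakend("chr1", 500_000)], g,
                                           ranges=[1000, 10_000])
        assert curve.observed.sum() == 0
        assert curve.expected_naive.sum() == 0

    def test_snvs_inside_neighborhoods_exceed_expected(self, rng):
        g = GenomeDef.from_lengths({"chr1": 10_000_000})
        be = breakend("chr1", 5_000_000)
        snvs = [SnvRecord("chr1", int(5_000_000 + o), "C", "A")
                for o in rng.integers(-5000, 5000, size=200)]
        curve = observed_vs_expected_curve(snvs, [be], g,
                                           ranges=[5_000, 50_000, 500_000])
        assert np.all(curve.observed >= curve.expected_naive)
        assert np.all(curve.observed >= curve.expected_corrected)

    def test_monotone_in_range(self, rng):
        g = GenomeDef.from_lengths({"chr1": 1_000_000})
        snvs = [SnvRecord("chr1", int(p), "C", "A")
                for p in rng.integers(1, 1_000_001, size=500)]
        bes = [breakend("chr1", int(p), i)
               for i, p in enumerate(rng.integers(1, 1_000_001, size=10))]
        curve = observed_vs_expected_curve(snvs, bes, g,
                                           ranges=[10, 100, 1000, 10_000, 100_000])
        assert np.all(np.diff(curve.observed) >= 0)
        assert np.all(np.diff(curve.expected_naive) >= 0)
        assert np.all(np.diff(curve.expected_corrected) >= 0)

    def test_corrected_le_naive_with_overlap(self, rng):
        g = GenomeDef.from_lengths({"chr1": 1_000_000})
        snvs = [SnvRecord("chr1", int(p), "C", "A")
                for p in rng.integers(1, 1_000_001, size=100)]
        bes = [breakend("chr1", int(p), i)
               for i, p in enumerate(rng.integers(400_000, 600_000, size=20))]
        curve = observed_vs_expected_curve(snvs, bes, g,
                                           ranges=[1000, 100_000, 500_000])
        assert np.all(curve.expected_corrected <= curve.expected_naive + 1e-9)

    def test_naive_matches_corrected_when_disjoint_unclipped(self):
        """Eq-equivalence on a constructed instance: the naive two-flank
        formula and the merged-length expectation agree up to the 1 bp
        discretization per site (2R vs 2R+1 covered bases)."""
        g = GenomeDef.from_lengths({"chr1": 100_000_000})
        bes = [breakend("chr1", 25_000_000, 0), breakend("chr1", 75_000_000, 1)]
        snvs = [SnvRecord("chr1", p, "C", "A")
                for p in range(1, 100_000_000, 100_000)]
        R = 1_000_000
        curve = observed_vs_expected_curve(snvs, bes, g, ranges=[R])
        n = len(snvs)
        assert curve.expected_naive[0] == pytest.approx(n / g.total_length * 2 * 2 * R)
        assert (curve.expected_corrected[0] - curve.expected_naive[0]
                == pytest.approx(n * 2 / g.total_length))

    def test_events_unit_counts_distinct_events(self):
        g = GenomeDef.from_lengths({"chr1": 1_000_000})
        bes = [SvBreakend("chr1", 100_000, "TRA", "e1"),
               SvBreakend("chr1", 900_000, "TRA", "e1")]
        snvs = [SnvRecord("chr1", 500_000, "C", "A")]
        by_be = observed_vs_expected_curve(snvs, bes, g, ranges=[1000])
        by_ev = observed_vs_expected_curve(snvs, bes, g, ranges=[1000],
                                           sv_unit="events")
        assert by_be.n_sv == 2 and by_ev.n_sv == 1
        assert by_be.expected_naive[0] == 2 * by_ev.expected_naive[0]
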