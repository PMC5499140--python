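import numpy as np
import pytest

from erscan import snp_filter
from erscan.sync_io import BiallelicSite
from helpers import make_site


def poly_site(pos, minor_f1=5, minor_f2=0, chrom="2L"):
    return make_site(
        chrom=chrom,
        pos=pos,
        F1={"A": 100 - minor_f1, "T": minor_f1},
        F2={"A": 100 - minor_f2, "T": minor_f2},
        E1={"A": 50, "T": 50},
        E2={"A": 50, "T": 50},
    )


def mono_site(pos, chrom="2L"):
    return poly_site(pos, minor_f1=0, minor_f2=0, chrom=chrom)


class TestCallSnps:
    def test_monomorphic_in_all_founders_excluded(self):
        assert snp_filter.call_snps([mono_site(10)], ["F1", "F2"]) == []

    def test_minor_allele_in_a_single_founder_replicate_suffices(self):
        sites = snp_filter.call_snps([poly_site(10, minor_f1=0, minor_f2=3)], ["F1", "F2"])
        assert len(sites) == 1

    def test_toy_file_emits_exactly_the_polymorphic_sites(self):
        toy = [mono_site(p) for p in (10, 20, 30, 50, 60, 80, 90)]
        toy += [poly_site(40), poly_site(70), poly_site(100)]
        toy.sort(key=lambda s: s.pos)
        called = snp_filter.call_snps(toy, ["F1", "F2"])
        assert [s.pos for s in called] == [40, 70, 100]

    def test_min_minor_count_threshold(self):
        site = poly_site(10, minor_f1=2)
        assert snp_filter.call_snps([site], ["F1", "F2"], min_minor_count=3) == []
        assert len(snp_filter.call_snps([site], ["F1", "F2"], min_minor_count=2)) == 1

    def test_report_tallies_conserve(self):
        report = snp_filter.FilterReport()
        toy = [mono_site(10), poly_site(20), mono_site(30)]
        out = snp_filter.call_snps(toy, ["F1", "F2"], report=report)
        assert report.n_in == 3 and report.n_out == len(out) == 1
        assert report.n_removed == report.n_in - report.n_out


class TestCoverageThresholds:
    def test_nearest_rank_against_sort_oracle(self, rng):
        depths = rng.permutation(np.arange(1, 1001))
        sites = [
            make_site(pos=i + 1, labels=("F1",), F1={"A": int(d)})
            for i, d in enumerate(depths)
        ]
        thr = snp_filter.coverage_thresholds(sites, quantile=0.01)
        ordered = np.sort(depths)
        assert thr.upper == ordered[int(np.ceil(0.99 * 1000)) - 1] == 990
        assert thr.lower == ordered[int(np.ceil(0.01 * 1000)) - 1] == 10
        assert thr.upper_basis == "F1"

    def test_constant_coverage_flagged_degenerate(self):
        sites = [make_site(pos=i + 1, labels=("F1",), F1={"A": 100}) for i in range(50)]
        with pytest.warns(UserWarning, match="degenerate"):
            thr = snp_filter.coverage_thresholds(sites)
        assert thr.degenerate and thr.upper == thr.lower == 100

    def test_upper_tail_uses_deepest_library(self):
        # F2 is the deepest library; its depths decide the upper bound
        sites = [
            make_site(pos=i + 1, labels=("F1", "F2"), F1={"A": 10}, F2={"A": 100 + i})
            for i in range(100)
        ]
        thr = snp_filter.coverage_thresholds(sites, quantile=0.05)
        assert thr.upper_basis == "F2"
        assert thr.upper == 100 + 94  # 95% nearest rank of 100..199

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            snp_filter.coverage_thresholds([])


def bisite(pos, counts, chrom="2L", labels=("F1", "E1")):
    return BiallelicSite(chrom, pos, "A", "T", tuple(counts), tuple(labels))


class TestApplyCoverageFilter:
    def test_all_pass_is_identity(self):
        sites = [bisite(1, [(50, 10), (40, 5)]), bisite(2, [(30, 0), (20, 2)])]
        thr = snp_filter.CoverageThresholds(upper=100, lower=10, upper_basis="F1")
        assert snp_filter.apply_coverage_filter(sites, thr) == sites

    def test_bounds_are_inclusive_for_removal(self):
        report = snp_filter.FilterReport()
        sites = [
            bisite(1, [(100, 0), (10, 0)]),  # focal depth == upper -> removed
            bisite(2, [(5, 0), (5, 0)]),  # total == lower -> removed
            bisite(3, [(50, 0), (30, 0)]),
        ]
        thr = snp_filter.CoverageThresholds(upper=100, lower=10, upper_basis="F1")
        kept = snp_filter.apply_coverage_filter(sites, thr, report=report)
        assert [s.pos for s in kept] == [3]
        assert report.removed == {"coverage_upper_tail": 1, "coverage_lower_tail": 1}

    def test_empty_input(self):
        thr = snp_filter.CoverageThresholds(upper=100, lower=10, upper_basis="F1")
        assert snp_filter.apply_coverage_filter([], thr) == []


class TestMaskIntervals:
    def test_bed_half_open_covers_one_based_position(self):
        site = bisite(100, [(10, 5), (10, 5)])
        # BED [99, 100) is exactly 1-based position 100
        assert snp_filter.mask_intervals([site], [("2L", 99, 100)]) == []
        assert snp_filter.mask_intervals([site], [("2L", 100, 101)]) == [site]
        assert snp_filter.mask_intervals([site], [("2L", 98, 99)]) == [site]

    def test_agrees_with_brute_force_point_oracle(self, rng):
        sites = [bisite(int(p), [(10, 5), (10, 5)]) for p in rng.integers(1, 1000, 200)]
        mask = [("2L", int(a), int(a + rng.integers(1, 50))) for a in rng.integers(0, 1000, 30)]
        kept = {id(s) for s in snp_filter.mask_intervals(sites, mask)}
        for site in sites:
            masked_oracle = any(
                start <= site.pos - 1 < end for _, start, end in mask
            )
            assert (id(site) not in kept) == masked_oracle

    def test_filters_commute(self, rng):
        sites = [
            bisite(int(p), [(int(a), int(b)), (int(c), int(d))])
            for p, a, b, c, d in zip(
                rng.choice(np.arange(1, 2000), 300, replace=False),
                rng.integers(0, 200, 300),
                rng.integers(0, 50, 300),
                rng.integers(0, 150, 300),
                rng.integers(0, 40, 300),
            )
        ]
        thr = snp_filter.CoverageThresholds(upper=180, lower=20, upper_basis="F1")
        mask = [("2L", 100, 400), ("2L", 900, 1500)]
        one = snp_filter.mask_intervals(snp_filter.apply_coverage_filter(sites, thr), mask)
        two = snp_filter.apply_coverage_filter(snp_filter.mask_intervals(sites, mask), thr)
        assert one == two


class TestDownsample:
    def test_ratio_one_leaves_counts_unchanged(self):
        sites = [bisite(i + 1, [(50, 10), (40, 5)]) for i in range(20)]
        mean = np.mean([[s.coverage(0), s.coverage(1)] for s in sites], axis=0).min()
        out = snp_filter.downsample_counts(sites, float(mean), seed=1)
        # the shallower library is already at the target and is untouched
        assert [s.counts[1] for s in out] == [s.counts[1] for s in sites]

    def test_mean_coverage_hits_target_within_one_percent(self, rng):
        n = 100_000
        maj = rng.poisson(80, n)
        mino = rng.poisson(20, n)
        sites = [
            bisite(i + 1, [(int(a), int(b))], labels=("F1",))
            for i, (a, b) in enumerate(zip(maj, mino))
        ]
        out = snp_filter.downsample_counts(sites, 50.0, seed=2)
        cov = np.array([s.coverage(0) for s in out])
        assert abs(cov.mean() - 50.0) / 50.0 < 0.01

    def test_expected_frequency_preserved(self, rng):
        n = 50_000
        sites = [bisite(i + 1, [(60, 40)], labels=("F1",)) for i in range(n)]
        out = snp_filter.downsample_counts(sites, 50.0, seed=3)
        freqs = np.array([s.frequency(0) for s in out if s.coverage(0) > 0])
        assert abs(freqs.mean() - 0.6) < 0.005

    def test_target_above_all_library_means_is_error(self):
        sites = [bisite(1, [(50, 10), (40, 5)])]
        with pytest.raises(ValueError):
            snp_filter.downsample_counts(sites, 100.0, seed=4)
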