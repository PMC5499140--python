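import numpy as np
import pandas as pd
import pytest

from erscan import regions


def cand(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "neg_log10_p"])


TOY = cand([("chr1", 150_000, 40.0), ("chr1", 250_000, 20.0)])
TOY_LENGTHS = {"chr1": 500_000}


class TestWindowScores:
    def test_hand_computed_toy(self):
        scores = regions.window_scores(TOY, TOY_LENGTHS)
        assert list(scores["start"]) == [1, 100_001, 200_001, 300_001]
        assert list(scores["end"]) == [200_000, 300_000, 400_000, 500_000]
        means = scores["mean_score"].tolist()
        assert means[0] == pytest.approx(40.0)
        assert means[1] == pytest.approx(30.0)
        assert means[2] == pytest.approx(20.0)
        assert np.isnan(means[3])
        assert list(scores["n_candidates"]) == [1, 2, 1, 0]

    def test_no_candidates_all_windows_undefined(self):
        scores = regions.window_scores(cand([]), TOY_LENGTHS)
        assert scores["mean_score"].isna().all()
        assert (scores["n_candidates"] == 0).all()

    def test_final_partial_window_is_scored(self):
        # windows stop once one reaches the chromosome end, so the last
        # window is the 150-kb remainder [300001, 450000]
        c = cand([("chr1", 440_000, 12.0)])
        scores = regions.window_scores(c, {"chr1": 450_000})
        last = scores.iloc[-1]
        assert (last["start"], last["end"]) == (300_001, 450_000)
        assert last["mean_score"] == pytest.approx(12.0)

    def test_candidate_beyond_chromosome_is_error(self):
        with pytest.raises(ValueError):
            regions.window_scores(cand([("chr1", 600_000, 5.0)]), TOY_LENGTHS)


class TestMergeRegions:
    def test_hand_computed_merge(self):
        scores = regions.window_scores(TOY, TOY_LENGTHS)
        merged, summary = regions.merge_regions(scores, cutoff=31.0,
                                                chrom_lengths=TOY_LENGTHS,
                                                candidates=TOY)
        assert len(merged) == 1
        r = merged.iloc[0]
        assert (r["chrom"], r["start"], r["end"]) == ("chr1", 1, 200_000)
        assert r["n_candidates"] == 1
        assert summary.total_bp == 200_000
        assert summary.fraction_of_genome == pytest.approx(0.4)

    def test_no_qualifying_windows(self):
        scores = regions.window_scores(TOY, TOY_LENGTHS)
        merged, summary = regions.merge_regions(scores, cutoff=100.0)
        assert merged.empty and summary.n_regions == 0

    def test_cutoff_is_strict(self):
        scores = regions.window_scores(TOY, TOY_LENGTHS)
        merged, _ = regions.merge_regions(scores, cutoff=40.0)
        assert merged.empty  # window mean exactly 40 does not qualify

    def test_adjacent_windows_union(self):
        c = cand([("chr1", 150_000, 50.0), ("chr1", 250_000, 50.0)])
        scores = regions.window_scores(c, TOY_LENGTHS)
        merged, _ = regions.merge_regions(scores, cutoff=31.0, candidates=c)
        assert len(merged) == 1
        assert (merged.iloc[0]["start"], merged.iloc[0]["end"]) == (1, 400_000)
        assert merged.iloc[0]["n_windows"] == 3
        assert merged.iloc[0]["n_candidates"] == 2

    def test_union_bounded_and_candidates_in_qualifying_windows(self, rng):
        lengths = {"cA": 2_000_000, "cB": 1_500_000}
        rows = []
        for chrom, length in lengths.items():
            pos = rng.choice(np.arange(1, length + 1), 300, replace=False)
            rows += [(chrom, int(p), float(rng.exponential(20))) for p in pos]
        c = cand(rows)
        scores = regions.window_scores(c, lengths)
        merged, summary = regions.merge_regions(scores, cutoff=25.0,
                                                chrom_lengths=lengths, candidates=c)
        for chrom, length in lengths.items():
            sub = merged[merged["chrom"] == chrom]
            assert (sub["end"] - sub["start"] + 1).sum() <= length
        # every region bp is the union of qualifying windows, so any
        # candidate inside a region must lie in at least one of them
        qual = scores[(scores["n_candidates"] > 0) & (scores["mean_score"] > 25.0)]
        for _, r in merged.iterrows():
            inside = c[(c.chrom == r["chrom"]) & (c.pos >= r["start"]) & (c.pos <= r["end"])]
            for _, snp in inside.iterrows():
                in_window = qual[
                    (qual.chrom == r["chrom"])
                    & (qual.start <= snp.pos)
                    & (qual.end >= snp.pos)
                ]
                assert not in_window.empty

    def test_nonoverlapping_windows_give_subset_coverage(self, rng):
        lengths = {"cA": 3_000_000}
        pos = rng.choice(np.arange(1, 3_000_001), 500, replace=False)
        c = cand([("cA", int(p), float(rng.exponential(25))) for p in pos])
        sliding = regions.window_scores(c, lengths, window=200_000, step=100_000)
        tiled = regions.window_scores(c, lengths, window=200_000, step=200_000)
        m_slide, _ = regions.merge_regions(sliding, cutoff=30.0)
        m_tile, _ = regions.merge_regions(tiled, cutoff=30.0)

        def covered(df):
            bp = set()
            for _, r in df.iterrows():
                bp.update(range(int(r["start"]) // 1000, int(r["end"]) // 1000 + 1))
            return bp

        assert covered(m_tile) <= covered(m_slide)

    def test_bed_output_is_zero_based_half_open(self, tmp_path):
        merged = pd.DataFrame(
            [{"chrom": "chr1", "start": 1, "end": 200_000,
              "n_windows": 1, "n_candidates": 3, "max_mean_score": 40.0}]
        )
        out = tmp_path / "r.bed"
        regions.regions_to_bed(merged, out)
        assert out.read_text() == "chr1\t0\t200000\n"


class TestAfcSummary:
    def _cands(self, founder, evolved):
        rows = []
        for i, (f, e) in enumerate(zip(founder, evolved)):
            rows.append(
                {"chrom": "2L", "pos": i + 1,
                 "founder_freq_1": f, "founder_freq_2": f, "founder_freq_3": f,
                 "evolved_freq_1": e, "evolved_freq_2": e, "evolved_freq_3": e,
                 "neg_log10_p": 40.0}
            )
        return pd.DataFrame(rows)

    def test_intermediate_final_frequencies_never_fixed(self):
        c = self._cands([0.2] * 5, [0.5] * 5)
        _, stats_ = regions.afc_summary(c, replicates=3)
        assert stats_["fixation_fraction"] == 0.0

    def test_fixation_fraction_counts_major_allele(self):
        evolved = [0.95, 0.92, 0.05, 0.5, 0.6, 0.7, 0.3, 0.4, 0.55, 0.45]
        # 0.95, 0.92 and 0.05 all have final major-allele frequency >= 0.9
        c = self._cands([0.5] * 10, evolved)
        _, stats_ = regions.afc_summary(c, replicates=3, fixation_threshold=0.9)
        assert stats_["fixation_fraction"] == pytest.approx(0.3)

    def test_rising_allele_polarization(self):
        c = self._cands([0.8, 0.2], [0.3, 0.7])
        table, _ = regions.afc_summary(c, replicates=3)
        # first SNP: major allele falls 0.8 -> 0.3, so rising allele starts 0.2
        assert table["start_freq"].tolist() == pytest.approx([0.2, 0.2])
        assert table["end_freq"].tolist() == pytest.approx([0.7, 0.7])
        assert (table["change"] >= 0).all()

    def test_empty_candidates(self):
        table, stats_ = regions.afc_summary(
            pd.DataFrame(columns=["chrom", "pos"]), replicates=3
        )
        assert table.empty and stats_["n"] == 0
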