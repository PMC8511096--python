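import numpy as np
import pandas as pd
import pytest
from scipy import stats

from setkit import (
    Peak,
    PeakSet,
    binned_coverage,
    call_peaks,
    frip,
    frip_per_cell,
    gene_signal_scores,
    window_correlation,
)
from setkit.genome_io import FragmentSet
from setkit.signal import SCALE_NUMERATOR, CoverageTrack


def make_frags(rows):
    return FragmentSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "cell_id"])
    )


class TestBinnedCoverage:
    def test_identity_scale_at_ten_million_reads(self):
        frags = make_frags([("chr1", 10, 60, "c")])
        tracks = binned_coverage(frags, {"chr1": 200}, bin_size=50,
                                 total_mapped=SCALE_NUMERATOR)
        assert tracks["chr1"].scale == 1.0
        # fragment [10, 60) overlaps bins 0 and 1 once each
        assert tracks["chr1"].values.tolist() == [1.0, 1.0, 0.0, 0.0]

    def test_fragment_counted_once_per_bin(self):
        frags = make_frags([("chr1", 0, 100, "c")])
        tracks = binned_coverage(frags, {"chr1": 100}, bin_size=50,
                                 total_mapped=1)
        np.testing.assert_allclose(
            tracks["chr1"].values, [SCALE_NUMERATOR, SCALE_NUMERATOR]
        )

    def test_matches_per_base_accumulation_oracle(self, rng):
        genome = {"chr1": 1000, "chr2": 600}
        rows = []
        for _ in range(300):
            chrom = rng.choice(["chr1", "chr2"])
            s = int(rng.integers(0, genome[chrom] - 30))
            rows.append((chrom, s, s + int(rng.integers(1, 30)), "c"))
        frags = make_frags(rows)
        tracks = binned_coverage(frags, genome, bin_size=25, total_mapped=300)
        for chrom, length in genome.items():
            expected = np.zeros(-(-length // 25))
            for c, s, e, _ in rows:
                if c != chrom:
                    continue
                # once per bin the fragment touches
                for b in range(s // 25, (e - 1) // 25 + 1):
                    expected[b] += 1
            np.testing.assert_allclose(
                tracks[chrom].counts, expected, atol=1e-9
            )

    def test_zero_total_mapped_rejected(self):
        with pytest.raises(ValueError):
            binned_coverage(make_frags([]), {"chr1": 100}, total_mapped=0)


def flat_track(n_bins, value, bin_size=50, chrom="chr1"):
    return CoverageTrack(chrom, bin_size, np.full(n_bins, float(value)))


class TestCallPeaks:
    def test_uniform_track_has_no_peaks(self):
        peaks = call_peaks({"chr1": flat_track(200, 5)}, p_threshold=1e-5)
        assert len(peaks) == 0

    def test_single_spike_yields_one_peak(self):
        values = np.full(400, 5.0)
        values[100:110] = 50.0  # 10x spike over 500 bp
        track = CoverageTrack("chr1", 50, values)
        lam = values.mean()
        # the Poisson tail separates spike from baseline at 1e-5
        assert stats.poisson.sf(49, lam) < 1e-5 < stats.poisson.sf(4, lam)
        peaks = call_peaks({"chr1": track}, mode="narrow", p_threshold=1e-5)
        assert len(peaks) == 1
        (p,) = peaks
        assert (p.start, p.end) == (5000, 5500)
        assert p.score == pytest.approx(50.0 / lam)

    def test_broad_merges_and_narrow_splits_an_800bp_gap(self):
        values = np.full(400, 2.0)
        values[40:52] = 40.0  # 600 bp run
        values[68:80] = 40.0  # second run, gap = 16 bins = 800 bp
        tracks = {"chr1": CoverageTrack("chr1", 50, values)}
        broad = call_peaks(tracks, mode="broad", p_threshold=1e-5)
        narrow = call_peaks(tracks, mode="narrow", p_threshold=1e-5)
        assert len(broad) == 1 and len(narrow) == 2
        assert (broad.peaks[0].start, broad.peaks[0].end) == (2000, 4000)

    def test_min_width_drops_short_runs(self):
        values = np.full(400, 2.0)
        values[40:44] = 40.0  # 200 bp < broad min width 500
        peaks = call_peaks({"chr1": CoverageTrack("chr1", 50, values)},
                           mode="broad", merge_gap_bp=0)
        assert len(peaks) == 0

    def test_empty_track_returns_empty_peakset(self):
        assert len(call_peaks({"chr1": flat_track(50, 0)})) == 0

    def test_output_sorted_disjoint_and_wide_enough(self, rng):
        values = rng.poisson(2, size=2000).astype(float)
        values[rng.choice(2000, 40, replace=False)] = 60.0
        peaks = call_peaks({"chr1": CoverageTrack("chr1", 50, values)},
                           mode="narrow", p_threshold=1e-4)
        prev_end = -1
        for p in peaks:
            assert p.start >= prev_end
            assert p.width >= 100
            prev_end = p.end


class TestFrip:
    PEAKS = PeakSet([Peak("chr1", 100, 200), Peak("chr1", 500, 700)])

    def test_all_inside(self):
        frags = make_frags([("chr1", 120, 180, "c"), ("chr1", 550, 600, "c")])
        assert frip(frags, self.PEAKS) == 1.0

    def test_disjoint(self):
        frags = make_frags([("chr1", 300, 400, "c"), ("chr2", 100, 200, "c")])
        assert frip(frags, self.PEAKS) == 0.0

    def test_mixed_matches_brute_force(self, rng):
        rows = []
        for _ in range(500):
            s = int(rng.integers(0, 900))
            rows.append(("chr1", s, s + int(rng.integers(1, 120)), "c"))
        frags = make_frags(rows)
        brute = sum(
            any(s < p.end and e > p.start for p in self.PEAKS)
            for _, s, e, _ in rows
        ) / len(rows)
        assert frip(frags, self.PEAKS) == pytest.approx(brute)

    def test_monotone_in_peaks(self, rng):
        rows = [("chr1", int(s), int(s) + 50, "c")
                for s in rng.integers(0, 2000, 200)]
        frags = make_frags(rows)
        more = PeakSet(list(self.PEAKS) + [Peak("chr1", 900, 1400)])
        assert frip(frags, more) >= frip(frags, self.PEAKS)

    def test_zero_fragments_returns_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(frip(make_frags([]), self.PEAKS))

    def test_per_cell_variant(self):
        frags = make_frags(
            [("chr1", 120, 180, "a"), ("chr1", 300, 400, "a"),
             ("chr1", 550, 600, "b")]
        )
        per = frip_per_cell(frags, self.PEAKS)
        assert per.to_dict() == {"a": 0.5, "b": 1.0}


class TestGeneSignalScores:
    def test_direct_arithmetic(self):
        # one 1,000 bp peak with 10 fragments; cell depth-normalised to 1e7
        peaks = PeakSet([Peak("chr1", 1000, 2000, name="pk")])
        rows = [("chr1", 1100 + i, 1150 + i, "c") for i in range(10)]
        frags = make_frags(rows)
        sm = gene_signal_scores(frags, peaks, {"pk": "gene1"})
        # depth 10 -> scale 1e6; 10 fragments * 1e6 / 1000 bp ... relative to
        # the definition: 10 * (1e7/10) / 1000 = 1e4
        assert sm.scores.loc["gene1", "c"] == pytest.approx(10 * 1e6 / 1000)

    def test_zero_overlap_zero_score(self):
        peaks = PeakSet([Peak("chr1", 1000, 2000, name="pk")])
        frags = make_frags([("chr1", 5000, 5100, "c")])
        sm = gene_signal_scores(frags, peaks, {"pk": "gene1"})
        assert sm.scores.loc["gene1", "c"] == 0.0

    def test_doubling_peak_width_halves_score(self):
        rows = [("chr1", 1100 + i, 1150 + i, "c") for i in range(10)]
        frags = make_frags(rows)
        narrow = PeakSet([Peak("chr1", 1000, 2000, name="pk")])
        wide = PeakSet([Peak("chr1", 1000, 3000, name="pk")])
        s1 = gene_signal_scores(frags, narrow, {"pk": "g"}).scores.loc["g", "c"]
        s2 = gene_signal_scores(frags, wide, {"pk": "g"}).scores.loc["g", "c"]
        assert s2 == pytest.approx(s1 / 2)

    def test_linear_in_fragment_counts(self):
        peaks = PeakSet([Peak("chr1", 0, 1000, name="pk"),
                         Peak("chr1", 5000, 6000, name="bg")])
        base = [("chr1", 10, 60, "c")] * 3 + [("chr1", 5010, 5060, "c")] * 3
        double = [("chr1", 10, 60, "c")] * 6 + [("chr1", 5010, 5060, "c")] * 6
        mapping = {"pk": "g", "bg": "h"}
        s1 = gene_signal_scores(make_frags(base), peaks, mapping).scores
        s2 = gene_signal_scores(make_frags(double), peaks, mapping).scores
        # doubling every count leaves the depth-normalised score unchanged,
        # while doubling only in-peak counts at fixed depth doubles it
        pd.testing.assert_frame_equal(s1, s2)

    def test_cell_with_no_fragments_flagged(self):
        peaks = PeakSet([Peak("chr1", 0, 1000, name="pk")])
        frags = make_frags([("chr1", 10, 60, "a")])
        with pytest.warns(UserWarning, match="zero fragments"):
            sm = gene_signal_scores(frags, peaks, {"pk": "g"},
                                    cell_ids=["a", "b"])
        assert sm.flagged_cells == ["b"]
        assert sm.scores.loc["g", "b"] == 0.0


class TestWindowCorrelation:
    def test_self_correlation_is_one(self, rng):
        t = {"chr1": CoverageTrack("chr1", 50, rng.poisson(5, 200).astype(float))}
        assert window_correlation(t, t) == pytest.approx(1.0)

    def test_anticorrelated_complement(self, rng):
        a = rng.poisson(5, 200).astype(float)
        ta = {"chr1": CoverageTrack("chr1", 1000, a)}
        tb = {"chr1": CoverageTrack("chr1", 1000, a.max() - a)}
        assert window_correlation(ta, tb, window_bp=1000) == pytest.approx(-1.0)

    def test_matches_textbook_pearson(self, rng):
        a = rng.poisson(5, 400).astype(float)
        b = rng.poisson(5, 400).astype(float)
        ta = {"chr1": CoverageTrack("chr1", 50, a)}
        tb = {"chr1": CoverageTrack("chr1", 50, b)}
        r = window_correlation(ta, tb, window_bp=1000)
        # independent aggregation to 20-bin windows + covariance formula
        aw = a.reshape(-1, 20).sum(axis=1)
        bw = b.reshape(-1, 20).sum(axis=1)
        expected = ((aw - aw.mean()) * (bw - bw.mean())).sum() / (
            np.sqrt(((aw - aw.mean()) ** 2).sum())
            * np.sqrt(((bw - bw.mean()) ** 2).sum())
        )
        assert r == pytest.approx(expected)

    def test_constant_track_warns_nan(self):
        ta = {"chr1": flat_track(100, 3.0)}
        tb = {"chr1": CoverageTrack("chr1", 50, np.arange(100, dtype=float))}
        with pytest.warns(UserWarning):
            assert np.isnan(window_correlation(ta, tb))


class TestTruthPeakRecovery:
    def test_caller_recovers_truth_peak_bases(self, mid_dataset):
        """At default thresholds and 10% background, called peaks cover >=95%
        of truth peak bases."""
        ds = mid_dataset
        genome = dict(ds.config.genome)
        mark = sorted(ds.fragments)[0]
        tracks = binned_coverage(ds.fragments[mark], genome)
        called = call_peaks(tracks, mode="narrow")
        truth_bases = covered = 0
        for tp in ds.truth_peaks:
            truth_bases += tp.width
            for cp in called:
                if cp.chrom == tp.chrom:
                    covered += max(
                        0, min(cp.end, tp.end) - max(cp.start, tp.start)
                    )
        assert covered / truth_bases >= 0.95
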