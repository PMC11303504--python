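"""Mean-shift segmentation, 2D merging, genotyping, and calling."""

import logging

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pycnvlite.baf_likelihood import BAFTrack, bin_baf_likelihood, max_baf
from pycnvlite.binned_signals import BinGrid, bin_read_depth, global_depth, to_copy_number
from pycnvlite.callers import (
    CallerParams,
    _merge_distance,
    call_2d,
    call_rd,
    estimate_bin_noise,
    genotype_segment,
    mean_shift_partition,
    merge_2d,
)
from pycnvlite.errors import PycnvliteError
from pycnvlite.simulate import CNVEvent, SampleSpec, event_state, simulate_sample
from pycnvlite.vcf_ingest import ContigMap

from conftest import make_cn_track


def least_squares_breakpoint(x):
    """Exhaustive oracle: the single split minimizing total within-SSE."""
    best, best_sse = None, np.inf
    for k in range(1, len(x)):
        a, b = x[:k], x[k:]
        sse = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
        if sse < best_sse:
            best, best_sse = k, sse
    return best


def synthetic_baf_track(grid, minor_per_bin, n_het=40, depth=60, seed=0):
    """BAF track with curves drawn from given per-bin minor fractions."""
    rng = np.random.default_rng(seed)
    chrom = grid.chroms[0]
    n_bins = grid.n_bins(chrom)
    G = 101
    curves = np.full((n_bins, G), np.nan)
    mb = np.full(n_bins, np.nan)
    nh = np.zeros(n_bins, dtype=np.int64)
    hd = np.zeros(n_bins, dtype=np.int64)
    for b, minor in enumerate(minor_per_bin):
        pairs = []
        for _ in range(n_het):
            q = minor if rng.random() < 0.5 else 1 - minor
            alt = rng.binomial(depth, q)
            pairs.append((depth - alt, alt))
        curves[b] = bin_baf_likelihood(pairs)
        mb[b] = max_baf(curves[b])
        nh[b] = n_het
        hd[b] = n_het * depth
    return BAFTrack(grid=grid, G=G, curves={chrom: curves}, max_baf={chrom: mb},
                    n_het={chrom: nh}, het_depth={chrom: hd})


class TestEstimateBinNoise:
    def test_constant_signal_has_zero_noise(self):
        assert estimate_bin_noise(make_cn_track(np.full(50, 2.0))) == 0.0

    def test_recovers_iid_gaussian_sigma(self):
        rng = np.random.default_rng(1)
        track = make_cn_track(2.0 + rng.normal(0, 0.2, 10_000))
        assert estimate_bin_noise(track) == pytest.approx(0.2, abs=0.01)

    def test_single_step_does_not_inflate_noise(self):
        x = np.r_[np.full(50, 2.0), np.full(50, 4.0)]
        assert estimate_bin_noise(make_cn_track(x)) == 0.0

    def test_too_few_bins_is_an_error(self):
        with pytest.raises(PycnvliteError):
            estimate_bin_noise(make_cn_track(np.full(5, 2.0)))


class TestMeanShiftPartition:
    def test_constant_signal_is_one_segment(self):
        segs = mean_shift_partition(make_cn_track(np.full(200, 2.0)), sigma=0.1)
        assert len(segs) == 1
        assert (segs[0].bin_start, segs[0].bin_end) == (0, 200)

    @pytest.mark.parametrize("height", [0.4, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("split", [40, 100, 160])
    def test_noiseless_step_matches_least_squares_oracle(self, height, split):
        x = np.r_[np.full(split, 2.0), np.full(200 - split, 2.0 + height)]
        segs = mean_shift_partition(make_cn_track(x), sigma=0.1)
        assert len(segs) == 2
        oracle = least_squares_breakpoint(x)
        assert abs(segs[0].bin_end - oracle) <= 1

    def test_noisy_step_breakpoint_is_near_oracle(self):
        rng = np.random.default_rng(9)
        x = np.r_[np.full(100, 2.0), np.full(100, 3.0)] + rng.normal(0, 0.1, 200)
        segs = mean_shift_partition(make_cn_track(x), sigma=0.1)
        oracle = least_squares_breakpoint(x)
        boundaries = [s.bin_end for s in segs[:-1]]
        assert min(abs(b - oracle) for b in boundaries) <= 1

    def test_masked_bins_split_segments(self):
        x = np.full(20, 2.0)
        x[10] = np.nan
        segs = mean_shift_partition(make_cn_track(x), sigma=0.1)
        spans = [(s.bin_start, s.bin_end) for s in segs]
        assert spans == [(0, 10), (11, 20)]

    def test_segments_tile_unmasked_bins(self):
        rng = np.random.default_rng(3)
        x = 2.0 + rng.normal(0, 0.15, 300)
        x[rng.random(300) < 0.1] = np.nan
        track = make_cn_track(x)
        segs = mean_shift_partition(track, sigma=0.15)
        assert sum(s.n_bins for s in segs) == np.isfinite(x).sum()
        for a, b in zip(segs[:-1], segs[1:]):
            assert a.bin_end <= b.bin_start


class TestCallRd:
    def test_clonal_deletion_segment_is_called_with_full_cell_fraction(self):
        from pycnvlite.callers import Segment

        rng = np.random.default_rng(4)
        x = np.r_[np.full(100, 2.0), np.full(50, 1.0), np.full(100, 2.0)]
        x = x + rng.normal(0, 0.1, 250)
        track = make_cn_track(x)
        segs = [Segment("chr1", 0, 100, float(x[:100].mean()), 100),
                Segment("chr1", 100, 150, float(x[100:150].mean()), 50),
                Segment("chr1", 150, 250, float(x[150:].mean()), 100)]
        calls = call_rd(segs, track)
        assert len(calls) == 1
        assert calls[0].type == "deletion"
        assert calls[0].cell_fraction == pytest.approx(1.0, abs=0.1)
        assert calls[0].caller == "rd"

    def test_mean_shift_plus_call_rd_cover_the_deletion(self):
        # the partition may split a long event; the deletion calls must
        # jointly cover it and nothing else
        rng = np.random.default_rng(4)
        x = np.r_[np.full(100, 2.0), np.full(50, 1.0), np.full(100, 2.0)]
        track = make_cn_track(x + rng.normal(0, 0.1, 250))
        calls = call_rd(mean_shift_partition(track, sigma=0.1), track)
        assert calls and all(c.type == "deletion" for c in calls)
        starts = min(c.start for c in calls)
        ends = max(c.end for c in calls)
        assert starts == pytest.approx(100 * 100_000, abs=2 * 100_000)
        assert ends == pytest.approx(150 * 100_000, abs=2 * 100_000)

    def test_shift_below_threshold_is_not_called(self):
        x = np.r_[np.full(100, 2.0), np.full(50, 2.05), np.full(100, 2.0)]
        track = make_cn_track(x)
        segs = mean_shift_partition(track, sigma=0.05)
        assert call_rd(segs, track) == []

    def test_short_noisy_segment_fails_significance(self):
        # 3 bins at cn 3 with sigma 0.5: t-test cannot establish the shift
        rng = np.random.default_rng(8)
        x = np.r_[2.0 + rng.normal(0, 0.5, 120), 3.0 + rng.normal(0, 0.5, 3),
                  2.0 + rng.normal(0, 0.5, 120)]
        track = make_cn_track(x)
        from pycnvlite.callers import Segment

        segs = [Segment("chr1", 0, 120, float(x[:120].mean()), 120),
                Segment("chr1", 120, 123, float(x[120:123].mean()), 3),
                Segment("chr1", 123, 243, float(x[123:].mean()), 120)]
        assert call_rd(segs, track) == []


class TestMerge2d:
    def test_homogeneous_diploid_chromosome_is_one_segment(self):
        rng = np.random.default_rng(6)
        grid_len = 120
        track = make_cn_track(2.0 + rng.normal(0, 0.05, grid_len))
        baf = synthetic_baf_track(track.grid, [0.5] * grid_len, seed=6)
        segs = merge_2d(track, baf, sigma=0.05)
        assert len(segs) == 1

    def test_baf_only_difference_forces_split(self):
        track = make_cn_track(np.full(100, 2.0))
        baf = synthetic_baf_track(track.grid, [0.5] * 50 + [0.2] * 50,
                                  n_het=100, depth=60, seed=7)
        segs = merge_2d(track, baf, sigma=0.05)
        assert len(segs) == 2
        assert abs(segs[0].bin_end - 50) <= 1

    def test_rd_only_difference_forces_split(self):
        rng = np.random.default_rng(12)
        x = np.r_[np.full(50, 2.0), np.full(50, 3.0)] + rng.normal(0, 0.1, 100)
        track = make_cn_track(x)
        baf = synthetic_baf_track(track.grid, [0.5] * 100, seed=12)
        segs = merge_2d(track, baf, sigma=0.1)
        assert len(segs) == 2
        assert abs(segs[0].bin_end - 50) <= 1

    def test_segments_tile_unmasked_bins(self):
        rng = np.random.default_rng(13)
        x = 2.0 + rng.normal(0, 0.1, 80)
        x[[7, 8, 40]] = np.nan
        track = make_cn_track(x)
        baf = synthetic_baf_track(track.grid, [0.5] * 80, seed=13)
        segs = merge_2d(track, baf, sigma=0.1)
        assert sum(s.n_bins for s in segs) == np.isfinite(x).sum()

    def test_merge_distance_is_symmetric_and_positive(self):
        a = bin_baf_likelihood([(20, 40)])
        b = bin_baf_likelihood([(30, 30)])
        d_ab = _merge_distance(2.0, 5, 2.3, 7, a, b, 0.1)
        d_ba = _merge_distance(2.3, 7, 2.0, 5, b, a, 0.1)
        assert d_ab == pytest.approx(d_ba, rel=1e-12)
        assert d_ab > 0


class TestGenotypeSegment:
    def test_clonal_deletion_limit(self):
        model, cn, f = genotype_segment(1.0, 0.0, 0.05, 0.02)
        assert (model, cn) == ("deletion", 1.0)
        assert f == pytest.approx(1.0, abs=1e-6)

    def test_diploid_observation_is_neutral(self):
        assert genotype_segment(2.0, 0.5, 0.05, 0.02)[0] == "neutral"

    def test_six_percent_subclonal_duplication(self):
        # invert BAF(f) = 1/(2+f) at f = 0.06 -> BAF 0.48544
        model, cn, f = genotype_segment(2.06, 0.4854, 0.005, 0.01)
        assert model == "duplication"
        assert f == pytest.approx(0.06, abs=0.005)

    @pytest.mark.parametrize("model", ["deletion", "duplication", "cnnloh"])
    @pytest.mark.parametrize("f", np.round(np.arange(0.1, 1.01, 0.1), 2).tolist())
    def test_forward_inverse_round_trip(self, model, f):
        cn_true, baf_true = event_state(model, f)
        got_model, _, got_f = genotype_segment(cn_true, baf_true, 0.02, 0.01)
        assert got_model == model
        assert got_f == pytest.approx(f, abs=0.005)


class TestCall2d:
    def _pipeline(self, spec, bin_size=100_000):
        variants, truth = simulate_sample(spec)
        grid = BinGrid(ContigMap(dict(spec.contigs)), bin_size)
        from pycnvlite.baf_likelihood import compute_baf_track

        rd = bin_read_depth(variants, grid)
        cn = to_copy_number(rd, global_depth(rd))
        baf = compute_baf_track(variants, grid)
        return cn, baf, truth

    def test_clonal_deletion_is_recovered_with_reciprocal_overlap(self):
        event = CNVEvent("chr1", 7_000_000, 12_000_000, "deletion", 1.0)
        spec = SampleSpec(contigs={"chr1": 30_000_000}, coverage=30, seed=21,
                          events=[event], truth_bin_size=100_000)
        cn, baf, _ = self._pipeline(spec)
        calls = [c for c in call_2d(cn, baf) if c.type == "deletion"]
        assert len(calls) == 1
        c = calls[0]
        ov = min(c.end, event.end) - max(c.start, event.start)
        assert ov / (event.end - event.start) >= 0.9
        assert ov / (c.end - c.start) >= 0.9

    def test_clonal_cnnloh_keeps_copy_number_two(self):
        event = CNVEvent("chr1", 7_000_000, 12_000_000, "cnnloh", 1.0)
        spec = SampleSpec(contigs={"chr1": 30_000_000}, coverage=30, seed=22,
                          events=[event], truth_bin_size=100_000)
        cn, baf, _ = self._pipeline(spec)
        calls = call_2d(cn, baf)
        cnnloh = [c for c in calls if c.type == "cnnloh"]
        assert len(cnnloh) == 1
        assert abs(cnnloh[0].cn - 2.0) < 0.1

    def test_flat_diploid_genome_yields_no_calls(self):
        spec = SampleSpec(contigs={"chr1": 30_000_000}, coverage=30, seed=23,
                          truth_bin_size=100_000)
        cn, baf, _ = self._pipeline(spec)
        assert call_2d(cn, baf) == []

    def test_missing_baf_track_falls_back_to_rd_caller(self, caplog):
        spec = SampleSpec(contigs={"chr1": 30_000_000}, coverage=30, seed=24,
                          events=[CNVEvent("chr1", 7_000_000, 12_000_000, "deletion", 1.0)],
                          truth_bin_size=100_000)
        cn, _, _ = self._pipeline(spec)
        with caplog.at_level(logging.WARNING):
            calls = call_2d(cn, None)
        assert any("RD caller" in r.message for r in caplog.records)
        assert calls and all(c.caller == "rd" for c in calls)
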