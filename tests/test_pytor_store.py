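"""HDF5 store round trips, region queries, and version guarding."""

import h5py
import numpy as np
import pytest

from pycnvlite.baf_likelihood import compute_baf_track
from pycnvlite.binned_signals import BinGrid, bin_read_depth, gc_correct
from pycnvlite.callers import CNVCall
from pycnvlite.errors import StoreError
from pycnvlite.pytor_store import FORMAT_VERSION, PytorStore
from pycnvlite.simulate import SampleSpec, simulate_sample
from pycnvlite.vcf_ingest import ContigMap


@pytest.fixture(scope="module")
def sample_tracks():
    spec = SampleSpec(contigs={"chr1": 900_000, "chr2": 500_000}, coverage=30, seed=13)
    variants, _ = simulate_sample(spec)
    grid = BinGrid(ContigMap(dict(spec.contigs)), 10_000)
    rd = bin_read_depth(variants, grid)
    baf = compute_baf_track(variants, grid)
    return rd, baf


def make_calls():
    return [
        CNVCall("chr1", 0, 100_000, "deletion", 1.0, 1.0, 1e-9, "2d", 10_000),
        CNVCall("chr1", 200_000, 500_000, "cnnloh", 2.0, 0.5, 1e-4, "2d", 10_000),
        CNVCall("chr2", 0, 300_000, "duplication", 3.0, 1.0, 1e-6, "2d", 10_000),
    ]


class TestSignalRoundTrip:
    def test_rd_track_round_trips_bitwise(self, sample_tracks, tmp_path):
        rd, _ = sample_tracks
        path = tmp_path / "s.h5"
        with PytorStore(path, "w") as store:
            store.set_meta(contigs=rd.grid.contigs, sample="s1")
            store.save_rd_track(rd)
        with PytorStore(path) as store:
            loaded = store.load_rd_track(10_000)
        for chrom in rd.grid.chroms:
            np.testing.assert_array_equal(loaded.raw[chrom], rd.raw[chrom])
            np.testing.assert_array_equal(loaded.n_var[chrom], rd.n_var[chrom])

    def test_gc_corrected_signal_round_trips(self, sample_tracks, tmp_path):
        rd, _ = sample_tracks
        rng = np.random.default_rng(5)
        gc = {c: np.clip(rng.normal(0.45, 0.03, rd.grid.n_bins(c)), 0, 1)
              for c in rd.grid.chroms}
        corrected = gc_correct(rd, gc, min_bins_per_class=10)
        path = tmp_path / "s.h5"
        with PytorStore(path, "w") as store:
            store.set_meta(contigs=rd.grid.contigs)
            store.save_rd_track(corrected)
        with PytorStore(path) as store:
            loaded = store.load_rd_track(10_000)
        for chrom in rd.grid.chroms:
            np.testing.assert_array_equal(
                loaded.corrected[chrom], corrected.corrected[chrom]
            )

    def test_baf_track_round_trips(self, sample_tracks, tmp_path):
        _, baf = sample_tracks
        path = tmp_path / "s.h5"
        with PytorStore(path, "w") as store:
            store.set_meta(contigs=baf.grid.contigs)
            store.save_baf_track(baf)
        with PytorStore(path) as store:
            loaded = store.load_baf_track(10_000)
        assert loaded.G == baf.G
        for chrom in baf.grid.chroms:
            np.testing.assert_array_equal(loaded.curves[chrom], baf.curves[chrom])
            np.testing.assert_array_equal(loaded.max_baf[chrom], baf.max_baf[chrom])
            np.testing.assert_array_equal(loaded.n_het[chrom], baf.n_het[chrom])
            np.testing.assert_array_equal(loaded.het_depth[chrom], baf.het_depth[chrom])

    def test_meta_lists_every_stored_bin_size(self, sample_tracks, tmp_path):
        from pycnvlite.baf_likelihood import rebin_baf
        from pycnvlite.binned_signals import rebin

        rd, baf = sample_tracks
        path = tmp_path / "s.h5"
        with PytorStore(path, "w") as store:
            store.set_meta(contigs=rd.grid.contigs)
            for factor in (1, 10, 100):
                store.save_rd_track(rebin(rd, factor))
                store.save_baf_track(rebin_baf(baf, factor))
            assert store.bin_sizes() == [10_000, 100_000, 1_000_000]

    def test_overwrite_replaces_dataset(self, sample_tracks, tmp_path):
        rd, _ = sample_tracks
        path = tmp_path / "s.h5"
        with PytorStore(path, "w") as store:
            store.set_meta(contigs=rd.grid.contigs)
            store.save_rd_track(rd)
            store.save_rd_track(rd)  # second save must not error or duplicate
            assert store.bin_sizes() == [10_000]


class TestRegionQuery:
    @pytest.fixture
    def store_path(self, sample_tracks, tmp_path):
        rd, _ = sample_tracks
        path = tmp_path / "s.h5"
        with PytorStore(path, "w") as store:
            store.set_meta(contigs=rd.grid.contigs)
            store.save_rd_track(rd)
        return path

    def test_full_chromosome_query(self, sample_tracks, store_path):
        rd, _ = sample_tracks
        with PytorStore(store_path) as store:
            values, first = store.load_region("chr1", 0, 900_000, 10_000, "raw")
        assert first == 0
        np.testing.assert_array_equal(values, rd.raw["chr1"])

    def test_single_bin_query(self, store_path):
        with PytorStore(store_path) as store:
            values, first = store.load_region("chr1", 0, 10_000, 10_000, "raw")
        assert (len(values), first) == (1, 0)

    def test_query_straddling_two_bins(self, store_path):
        with PytorStore(store_path) as store:
            values, first = store.load_region("chr1", 9_000, 11_000, 10_000, "raw")
        assert (len(values), first) == (2, 0)

    def test_unknown_signal_lists_available_keys(self, store_path):
        with PytorStore(store_path) as store:
            with pytest.raises(StoreError, match="raw"):
                store.load_region("chr1", 0, 10_000, 10_000, "bogus")
            with pytest.raises(StoreError):
                store.load_region("chr9", 0, 10_000, 10_000, "raw")


class TestCalls:
    def test_round_trip_identity(self, tmp_path):
        path = tmp_path / "s.h5"
        calls = make_calls()
        with PytorStore(path, "w") as store:
            store.save_calls(calls, "2d", 10_000)
        with PytorStore(path) as store:
            assert store.load_calls("2d", 10_000) == calls

    def test_absent_table_loads_empty(self, tmp_path):
        with PytorStore(tmp_path / "s.h5", "w") as store:
            assert store.load_calls("2d", 10_000) == []

    def test_two_callers_are_independent(self, tmp_path):
        calls = make_calls()
        with PytorStore(tmp_path / "s.h5", "w") as store:
            store.save_calls(calls[:1], "rd", 10_000)
            store.save_calls(calls[1:], "2d", 10_000)
            assert store.load_calls("rd", 10_000) == calls[:1]
            assert store.load_calls("2d", 10_000) == calls[1:]


class TestVersioning:
    def test_foreign_version_is_rejected(self, tmp_path):
        path = tmp_path / "old.h5"
        with h5py.File(path, "w") as h5:
            h5.create_group("meta").attrs["format_version"] = "someone-else-9"
        with pytest.raises(StoreError, match=FORMAT_VERSION):
            PytorStore(path)

    def test_missing_file_read_is_an_error(self, tmp_path):
        with pytest.raises(StoreError):
            PytorStore(tmp_path / "absent.h5")
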