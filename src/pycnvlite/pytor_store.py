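"""HDF5 "pytor-style" persistence of binned signals, BAF curves, and calls.

Layout (format version ``pycnvlite-1``):

    /meta                    attrs: format_version, sample, params (JSON);
                             datasets: contig_names, contig_lengths, bin_sizes
    /rd/<chrom>/raw_<size>   float64, NaN = masked bin
    /rd/<chrom>/gc_<size>    GC-corrected RD (only when computed)
    /rd/<chrom>/nvar_<size>  int64 contributing-variant counts
    /snp/<chrom>/lik_<size>    (n_bins, G) normalized BAF curves, NaN rows masked
    /snp/<chrom>/maxbaf_<size> folded ML BAF per bin
    /snp/<chrom>/nhet_<size>   int64 het counts
    /snp/<chrom>/hdep_<size>   int64 summed het-site read depths
    /calls/<caller>_<size>   structured table of call records

Masks are encoded as NaN and reconstructed on load. Datasets are
gzip-compressed (level 4). The naming is this package's own documented
scheme; byte-level compatibility with other tools' HDF5 internals is not
claimed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import h5py
import numpy as np

from .baf_likelihood import BAFTrack
from .binned_signals import BinGrid, RDTrack
from .callers import CNVCall
from .errors import StoreError
from .vcf_ingest import ContigMap

FORMAT_VERSION = "pycnvlite-1"

_CALL_DTYPE = np.dtype(
    [
        ("chrom", "S64"),
        ("start", "i8"),
        ("end", "i8"),
        ("type", "S16"),
        ("cn", "f8"),
        ("cell_fraction", "f8"),
        ("p_value", "f8"),
        ("caller", "S16"),
        ("bin_size", "i8"),
    ]
)

_COMP = dict(compression="gzip", compression_opts=4)

_SIGNAL_GROUPS = {
    "raw": ("rd", "raw"),
    "corrected": ("rd", "gc"),
    "gc": ("rd", "gc"),
    "nvar": ("rd", "nvar"),
    "lik": ("snp", "lik"),
    "maxbaf": ("snp", "maxbaf"),
    "nhet": ("snp", "nhet"),
    "hetdepth": ("snp", "hdep"),
}


class PytorStore:
    """Read/write access to one pytor-style HDF5 file.

    Usable as a context manager. Opening an existing file whose
    format_version differs from :data:`FORMAT_VERSION` is an error.
    """

    def __init__(self, path: Union[str, Path], mode: str = "r"):
        self.path = Path(path)
        try:
            self._h5 = h5py.File(self.path, mode)
        except (OSError, ValueError) as exc:
            raise StoreError(f"cannot open store {self.path} ({mode!r}): {exc}") from exc
        meta = self._h5.get("meta")
        if meta is not None:
            version = meta.attrs.get("format_version")
            if version != FORMAT_VERSION:
                self._h5.close()
                raise StoreError(
                    f"{self.path}: format version {version!r} != {FORMAT_VERSION!r}"
                )
        elif mode in ("w", "a", "r+", "x"):
            grp = self._h5.create_group("meta")
            grp.attrs["format_version"] = FORMAT_VERSION

    # -- lifecycle ---------------------------------------------------------
    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "PytorStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- meta --------------------------------------------------------------
    def set_meta(
        self,
        contigs: Optional[ContigMap] = None,
        sample: Optional[str] = None,
        params: Optional[dict] = None,
    ) -> None:
        meta = self._h5.require_group("meta")
        if sample is not None:
            meta.attrs["sample"] = sample
        if params is not None:
            meta.attrs["params"] = json.dumps(params)
        if contigs is not None:
            for name in ("contig_names", "contig_lengths"):
                if name in meta:
                    del meta[name]
            names = np.array([n.encode() for n in contigs.names])
            meta.create_dataset("contig_names", data=names)
            meta.create_dataset(
                "contig_lengths", data=np.array([contigs[n] for n in contigs.names], dtype="i8")
            )

    def contigs(self) -> ContigMap:
        meta = self._h5["meta"]
        if "contig_names" not in meta:
            raise StoreError(f"{self.path}: no contig metadata stored")
        names = [n.decode() for n in meta["contig_names"][:]]
        lengths = meta["contig_lengths"][:]
        return ContigMap({n: int(l) for n, l in zip(names, lengths)})

    def sample(self) -> Optional[str]:
        return self._h5["meta"].attrs.get("sample")

    def params(self) -> dict:
        raw = self._h5["meta"].attrs.get("params")
        return json.loads(raw) if raw else {}

    def bin_sizes(self) -> List[int]:
        meta = self._h5["meta"]
        if "bin_sizes" not in meta:
            return []
        return sorted(int(s) for s in meta["bin_sizes"][:])

    def _register_bin_size(self, size: int) -> None:
        meta = self._h5["meta"]
        sizes = set(self.bin_sizes()) | {int(size)}
        if "bin_sizes" in meta:
            del meta["bin_sizes"]
        meta.create_dataset("bin_sizes", data=np.array(sorted(sizes), dtype="i8"))

    # -- signals -----------------------------------------------------------
    def _write(self, group: str, chrom: str, name: str, data: np.ndarray) -> None:
        grp = self._h5.require_group(f"{group}/{chrom}")
        if name in grp:
            del grp[name]
        grp.create_dataset(name, data=data, **_COMP)

    def save_rd_track(self, track: RDTrack) -> None:
        size = track.grid.bin_size
        for chrom in track.grid.chroms:
            self._write("rd", chrom, f"raw_{size}", track.raw[chrom])
            self._write("rd", chrom, f"nvar_{size}", track.n_var[chrom].astype("i8"))
            if track.corrected is not None:
                self._write("rd", chrom, f"gc_{size}", track.corrected[chrom])
        self._register_bin_size(size)

    def save_baf_track(self, track: BAFTrack) -> None:
        size = track.grid.bin_size
        for chrom in track.grid.chroms:
            self._write("snp", chrom, f"lik_{size}", track.curves[chrom])
            self._write("snp", chrom, f"maxbaf_{size}", track.max_baf[chrom])
            self._write("snp", chrom, f"nhet_{size}", track.n_het[chrom].astype("i8"))
            self._write("snp", chrom, f"hdep_{size}", track.het_depth[chrom].astype("i8"))
        self._register_bin_size(size)

    def save_signals(self, rd_tracks: Sequence[RDTrack], baf_tracks: Sequence[BAFTrack]) -> None:
        for t in rd_tracks:
            self.save_rd_track(t)
        for t in baf_tracks:
            self.save_baf_track(t)

    def load_rd_track(self, size: int) -> RDTrack:
        contigs = self.contigs()
        grid = BinGrid(contigs, size)
        raw, n_var = {}, {}
        corrected: Optional[Dict[str, np.ndarray]] = {}
        for chrom in contigs.names:
            grp = self._h5.get(f"rd/{chrom}")
            if grp is None or f"raw_{size}" not in grp:
                raise StoreError(
                    f"{self.path}: no RD at bin size {size} for {chrom}; "
                    f"available: {self.list_contents()}"
                )
            raw[chrom] = grp[f"raw_{size}"][:]
            n_var[chrom] = grp[f"nvar_{size}"][:]
            if f"gc_{size}" in grp:
                corrected[chrom] = grp[f"gc_{size}"][:]
        if corrected is not None and len(corrected) != len(contigs):
            corrected = None
        return RDTrack(grid=grid, raw=raw, n_var=n_var, corrected=corrected or None)

    def load_baf_track(self, size: int) -> BAFTrack:
        contigs = self.contigs()
        grid = BinGrid(contigs, size)
        curves, maxb, n_het, het_depth = {}, {}, {}, {}
        G = None
        for chrom in contigs.names:
            grp = self._h5.get(f"snp/{chrom}")
            if grp is None or f"lik_{size}" not in grp:
                raise StoreError(
                    f"{self.path}: no BAF at bin size {size} for {chrom}; "
                    f"available: {self.list_contents()}"
                )
            curves[chrom] = grp[f"lik_{size}"][:]
            maxb[chrom] = grp[f"maxbaf_{size}"][:]
            n_het[chrom] = grp[f"nhet_{size}"][:]
            if f"hdep_{size}" in grp:
                het_depth[chrom] = grp[f"hdep_{size}"][:]
            G = curves[chrom].shape[1]
        return BAFTrack(grid=grid, G=int(G), curves=curves, max_baf=maxb, n_het=n_het,
                        het_depth=het_depth or None)

    def load_region(
        self, chrom: str, start_bp: int, end_bp: int, size: int, signal: str
    ) -> Tuple[np.ndarray, int]:
        """Bins overlapping [start_bp, end_bp); returns (values, first bin index)."""
        if signal not in _SIGNAL_GROUPS:
            raise StoreError(
                f"unknown signal {signal!r}; available: {sorted(_SIGNAL_GROUPS)}"
            )
        group, prefix = _SIGNAL_GROUPS[signal]
        dset = self._h5.get(f"{group}/{chrom}/{prefix}_{size}")
        if dset is None:
            raise StoreError(
                f"{self.path}: no dataset {group}/{chrom}/{prefix}_{size}; "
                f"available: {self.list_contents()}"
            )
        first = start_bp // size
        last = -(-end_bp // size)  # ceil: bins overlapping the half-open range
        first = max(first, 0)
        last = min(last, dset.shape[0])
        if last <= first:
            return np.empty((0,) + dset.shape[1:]), first
        return dset[first:last], first

    # -- calls -------------------------------------------------------------
    def save_calls(self, calls: Sequence[CNVCall], caller: str, size: int) -> None:
        table = np.zeros(len(calls), dtype=_CALL_DTYPE)
        for i, c in enumerate(calls):
            table[i] = (
                c.chrom.encode(), c.start, c.end, c.type.encode(), c.cn,
                c.cell_fraction, c.p_value, c.caller.encode(), c.bin_size,
            )
        grp = self._h5.require_group("calls")
        name = f"{caller}_{size}"
        if name in grp:
            del grp[name]
        grp.create_dataset(name, data=table, **_COMP)

    def load_calls(self, caller: str, size: int) -> List[CNVCall]:
        """Stored call table, or an empty list when none was written."""
        dset = self._h5.get(f"calls/{caller}_{size}")
        if dset is None:
            return []
        return [
            CNVCall(
                chrom=row["chrom"].decode(),
                start=int(row["start"]),
                end=int(row["end"]),
                type=row["type"].decode(),
                cn=float(row["cn"]),
                cell_fraction=float(row["cell_fraction"]),
                p_value=float(row["p_value"]),
                caller=row["caller"].decode(),
                bin_size=int(row["bin_size"]),
            )
            for row in dset[:]
        ]

    # -- inspection --------------------------------------------------------
    def list_contents(self) -> List[Tuple[str, str, int]]:
        """Every stored (signal, chrom, bin_size) triple, plus call tables."""
        out: List[Tuple[str, str, int]] = []
        for group, label in (("rd", "rd"), ("snp", "snp")):
            g = self._h5.get(group)
            if g is None:
                continue
            for chrom in g:
                for name in g[chrom]:
                    prefix, _, size = name.rpartition("_")
                    out.append((f"{label}/{prefix}", chrom, int(size)))
        g = self._h5.get("calls")
        if g is not None:
            for name in g:
                caller, _, size = name.rpartition("_")
                out.append((f"calls/{caller}", "*", int(size)))
        return sorted(out)
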