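"""Binned read-depth signals: binning, CN normalization, GC correction, rebinning.

The RD signal of a bin is the arithmetic mean DP over the variant sites it
contains — a coverage-calibrated estimate that does not depend on the local
SNP density. Bins without any variant are masked (NaN) and stay masked
through every downstream step; they are never interpolated.

CN units: the genome-wide median depth of unmasked autosomal bins maps to
copy number 2 (diploid baseline), so a heterozygous deletion sits near 1 and
a single-copy gain near 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import GridMismatchError, PycnvliteError
from .vcf_ingest import ContigMap, VariantRecord

#: chromosome basenames excluded from the diploid-baseline estimate
SEX_MITO_NAMES = frozenset({"X", "Y", "M", "MT"})


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width binning of a contig map.

    A 1-based position p falls in bin floor((p-1)/bin_size); bins are
    0-based half-open [i*size, (i+1)*size) and the last bin may be short.
    """

    contigs: ContigMap
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise PycnvliteError(f"bin_size must be positive, got {self.bin_size}")

    @property
    def chroms(self) -> Sequence[str]:
        return self.contigs.names

    def n_bins(self, chrom: str) -> int:
        return -(-self.contigs[chrom] // self.bin_size)

    def bin_index(self, pos: int) -> int:
        return (pos - 1) // self.bin_size

    def same_as(self, other: "BinGrid") -> bool:
        return self.bin_size == other.bin_size and self.contigs.lengths == other.contigs.lengths


@dataclass
class RDTrack:
    """Per-chromosome binned read depth (raw and optionally GC-corrected).

    ``raw[chrom]`` is the mean DP per bin with NaN where no variant fell in
    the bin; ``n_var[chrom]`` counts contributing variants (0 <=> masked).
    """

    grid: BinGrid
    raw: Dict[str, np.ndarray]
    n_var: Dict[str, np.ndarray]
    corrected: Optional[Dict[str, np.ndarray]] = None

    def mask(self, chrom: str) -> np.ndarray:
        return self.n_var[chrom] == 0

    def signal(self, which: str = "raw") -> Dict[str, np.ndarray]:
        if which == "raw":
            return self.raw
        if which == "corrected":
            if self.corrected is None:
                raise PycnvliteError("track has no GC-corrected signal")
            return self.corrected
        raise PycnvliteError(f"unknown signal {which!r}")

    def best_signal(self) -> Dict[str, np.ndarray]:
        """GC-corrected values when available, raw otherwise."""
        return self.corrected if self.corrected is not None else self.raw


@dataclass
class CNTrack:
    """A binned signal in copy-number units (NaN = masked)."""

    grid: BinGrid
    values: Dict[str, np.ndarray]

    def unmasked(self) -> np.ndarray:
        """All finite values concatenated in chromosome order."""
        parts = [v[np.isfinite(v)] for v in self.values.values()]
        return np.concatenate(parts) if parts else np.empty(0)


def bin_read_depth(variants: Iterable[VariantRecord], grid: BinGrid) -> RDTrack:
    """Aggregate per-variant DP into per-bin means on ``grid``."""
    per_chrom_pos: Dict[str, list] = {c: [] for c in grid.chroms}
    per_chrom_dp: Dict[str, list] = {c: [] for c in grid.chroms}
    for v in variants:
        if v.chrom not in per_chrom_pos:
            raise PycnvliteError(f"variant {v.chrom}:{v.pos} on contig absent from grid")
        if v.pos > grid.contigs[v.chrom]:
            raise PycnvliteError(
                f"variant {v.chrom}:{v.pos} beyond contig length {grid.contigs[v.chrom]}"
            )
        per_chrom_pos[v.chrom].append(v.pos)
        per_chrom_dp[v.chrom].append(v.dp)
    raw: Dict[str, np.ndarray] = {}
    n_var: Dict[str, np.ndarray] = {}
    for chrom in grid.chroms:
        n = grid.n_bins(chrom)
        pos = np.asarray(per_chrom_pos[chrom], dtype=np.int64)
        dp = np.asarray(per_chrom_dp[chrom], dtype=np.float64)
        idx = (pos - 1) // grid.bin_size if pos.size else pos
        counts = np.bincount(idx, minlength=n).astype(np.int64)
        sums = np.bincount(idx, weights=dp, minlength=n)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        raw[chrom] = mean
        n_var[chrom] = counts
    return RDTrack(grid=grid, raw=raw, n_var=n_var)


def _is_autosome(name: str) -> bool:
    base = name[3:] if name.lower().startswith("chr") else name
    return base.upper() not in SEX_MITO_NAMES


def global_depth(track: RDTrack, signal: str = "raw") -> float:
    """Median depth over unmasked autosomal bins (the diploid baseline).

    Median rather than mean so large CNAs in cancer samples do not drag the
    baseline. Falls back to all contigs when every contig looks like a sex
    or mitochondrial chromosome.
    """
    values = track.signal(signal)
    chroms = [c for c in track.grid.chroms if _is_autosome(c)] or list(track.grid.chroms)
    pooled = np.concatenate([values[c][~track.mask(c)] for c in chroms]) if chroms else np.empty(0)
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise PycnvliteError("cannot estimate global depth: all bins are masked")
    return float(np.median(pooled))


def to_copy_number(track: RDTrack, global_depth_value: float, signal: str = "raw") -> CNTrack:
    """Scale depth to CN units: cn = 2 * rd / global depth; mask preserved."""
    if not global_depth_value > 0:
        raise PycnvliteError(f"global depth must be positive, got {global_depth_value}")
    values = track.signal(signal)
    cn = {c: 2.0 * values[c] / global_depth_value for c in track.grid.chroms}
    return CNTrack(grid=track.grid, values=cn)


def gc_correct(
    track: RDTrack,
    gc_table: Dict[str, np.ndarray],
    class_width: float = 0.01,
    min_bins_per_class: int = 100,
) -> RDTrack:
    """Fill ``corrected`` by GC-class mean scaling.

    Bins are stratified into GC classes of width ``class_width`` (fraction,
    default one percentage point); corrected = raw * global_mean /
    class_mean. Classes with fewer than ``min_bins_per_class`` unmasked bins
    are pooled with the nearest neighboring class until large enough. Bins
    with missing GC keep their raw value.
    """
    for chrom in track.grid.chroms:
        if chrom not in gc_table or len(gc_table[chrom]) != track.grid.n_bins(chrom):
            raise GridMismatchError(f"GC table does not match grid on contig {chrom!r}")
    n_classes = int(round(1.0 / class_width))
    chroms = list(track.grid.chroms)
    raw_all = np.concatenate([track.raw[c] for c in chroms])
    gc_all = np.concatenate([np.asarray(gc_table[c], dtype=float) for c in chroms])
    usable = np.isfinite(raw_all) & np.isfinite(gc_all)
    cls = np.full(raw_all.shape, -1, dtype=np.int64)
    cls[usable] = np.minimum((gc_all[usable] / class_width).astype(np.int64), n_classes - 1)

    present = np.unique(cls[cls >= 0])
    # group classes left-to-right, then pool undersized groups with the
    # nearest neighbor (by class distance, ties toward the lower class)
    groups = [[int(c)] for c in present]
    counts = [int(np.sum((cls == c) & usable)) for c in present]
    while len(groups) > 1:
        small = [i for i, n in enumerate(counts) if n < min_bins_per_class]
        if not small:
            break
        i = min(small, key=lambda k: counts[k])
        if i == 0:
            j = 1
        elif i == len(groups) - 1:
            j = i - 1
        else:
            left_gap = groups[i][0] - groups[i - 1][-1]
            right_gap = groups[i + 1][0] - groups[i][-1]
            j = i - 1 if left_gap <= right_gap else i + 1
        a, b = sorted((i, j))
        groups[a] = groups[a] + groups[b]
        counts[a] = counts[a] + counts[b]
        del groups[b], counts[b]

    group_of = {c: gi for gi, grp in enumerate(groups) for c in grp}
    global_mean = float(np.mean(raw_all[usable])) if usable.any() else np.nan
    scale = np.ones(raw_all.shape)
    for gi in range(len(groups)):
        members = usable & np.isin(cls, groups[gi])
        class_mean = float(np.mean(raw_all[members]))
        if class_mean > 0:
            scale[members] = global_mean / class_mean
    corrected_all = np.where(usable, raw_all * scale, raw_all)

    corrected: Dict[str, np.ndarray] = {}
    offset = 0
    for chrom in chroms:
        n = track.grid.n_bins(chrom)
        corrected[chrom] = corrected_all[offset : offset + n].copy()
        offset += n
    return RDTrack(grid=track.grid, raw=track.raw, n_var=track.n_var, corrected=corrected)


def _rebin_weighted(values: np.ndarray, weights: np.ndarray, factor: int) -> np.ndarray:
    n_coarse = -(-len(values) // factor)
    pad = n_coarse * factor - len(values)
    v = np.pad(values, (0, pad), constant_values=np.nan).reshape(n_coarse, factor)
    w = np.pad(weights.astype(float), (0, pad)).reshape(n_coarse, factor)
    prod = np.where(w > 0, np.nan_to_num(v) * w, 0.0)
    wsum = w.sum(axis=1)
    with np.errstate(invalid="ignore"):
        out = np.where(wsum > 0, prod.sum(axis=1) / np.maximum(wsum, 1e-300), np.nan)
    return out


def rebin(track: RDTrack, factor: int) -> RDTrack:
    """Coarsen a track by an integer factor using n_var-weighted means.

    Coarse n_var is the sum of constituents; a coarse bin is masked iff all
    its constituents are masked. Associative: rebin(t, a*b) equals
    rebin(rebin(t, a), b).
    """
    if factor < 1:
        raise PycnvliteError(f"rebin factor must be >= 1, got {factor}")
    if factor == 1:
        return track
    grid = BinGrid(track.grid.contigs, track.grid.bin_size * factor)
    raw, n_var = {}, {}
    corrected: Optional[Dict[str, np.ndarray]] = {} if track.corrected is not None else None
    for chrom in track.grid.chroms:
        w = track.n_var[chrom]
        raw[chrom] = _rebin_weighted(track.raw[chrom], w, factor)
        if corrected is not None:
            corrected[chrom] = _rebin_weighted(track.corrected[chrom], w, factor)
        n_coarse = grid.n_bins(chrom)
        pad = n_coarse * factor - len(w)
        n_var[chrom] = np.pad(w, (0, pad)).reshape(n_coarse, factor).sum(axis=1)
    return RDTrack(grid=grid, raw=raw, n_var=n_var, corrected=corrected)


def rebin_gc(gc_table: Dict[str, np.ndarray], grid: BinGrid, factor: int) -> Dict[str, np.ndarray]:
    """Average a per-bin GC table onto a ``factor``-times coarser grid."""
    out = {}
    for chrom in grid.chroms:
        v = np.asarray(gc_table[chrom], dtype=float)
        n_coarse = -(-len(v) // factor)
        pad = n_coarse * factor - len(v)
        vv = np.pad(v, (0, pad), constant_values=np.nan).reshape(n_coarse, factor)
        with np.errstate(invalid="ignore"):
            out[chrom] = np.nanmean(vv, axis=1)
    return out


def read_gc_table(path: Union[str, Path], grid: BinGrid) -> Dict[str, np.ndarray]:
    """Load a 3-column TSV ``chrom  bin_start(0-based)  gc_fraction``."""
    df = pd.read_csv(path, sep="\t", names=["chrom", "start", "gc"], comment="#")
    table = {c: np.full(grid.n_bins(c), np.nan) for c in grid.chroms}
    for chrom, sub in df.groupby("chrom"):
        if chrom not in table:
            continue
        idx = (sub["start"].to_numpy() // grid.bin_size).astype(int)
        ok = (idx >= 0) & (idx < len(table[chrom]))
        table[chrom][idx[ok]] = sub["gc"].to_numpy()[ok]
    bad = [
        c for c in table
        for v in [table[c][np.isfinite(table[c])]]
        if v.size and (v.min() < 0 or v.max() > 1)
    ]
    if bad:
        raise PycnvliteError(f"GC fractions outside [0,1] on contigs {bad}")
    return table


def export_rd_tsv(track: RDTrack, path: Union[str, Path]) -> Path:
    """Write ``chrom  start  end  raw  corrected  n_var`` (0-based half-open)."""
    rows = []
    size = track.grid.bin_size
    for chrom in track.grid.chroms:
        length = track.grid.contigs[chrom]
        raw = track.raw[chrom]
        corr = track.corrected[chrom] if track.corrected is not None else raw
        for i in range(len(raw)):
            rows.append(
                (chrom, i * size, min((i + 1) * size, length), raw[i], corr[i],
                 int(track.n_var[chrom][i]))
            )
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "raw", "corrected", "n_var"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return Path(path)


def export_cn_tsv(track: CNTrack, path: Union[str, Path]) -> Path:
    """Write ``chrom  start  end  cn`` for a CN-unit track."""
    rows = []
    size = track.grid.bin_size
    for chrom in track.grid.chroms:
        length = track.grid.contigs[chrom]
        for i, v in enumerate(track.values[chrom]):
            rows.append((chrom, i * size, min((i + 1) * size, length), v))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    return Path(path)


def read_cn_tsv(path: Union[str, Path], value_column: Optional[str] = None) -> CNTrack:
    """Load a binned-signal TSV back into a :class:`CNTrack`.

    Accepts the 4-column ``cn`` export or the 6-column RD export (then
    ``value_column`` picks the signal, default the 4th column).
    """
    df = pd.read_csv(path, sep="\t")
    if value_column is None:
        value_column = df.columns[3]
    starts = df.groupby("chrom", sort=False)
    lengths = {str(c): int(sub["end"].max()) for c, sub in starts}
    widths = (df["end"] - df["start"]).to_numpy()
    bin_size = int(np.max(widths)) if len(df) else 1
    grid = BinGrid(ContigMap(lengths), bin_size)
    values = {c: np.full(grid.n_bins(c), np.nan) for c in lengths}
    for chrom, sub in starts:
        idx = (sub["start"].to_numpy() // bin_size).astype(int)
        values[str(chrom)][idx] = sub[value_column].to_numpy(dtype=float)
    return CNTrack(grid=grid, values=values)
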