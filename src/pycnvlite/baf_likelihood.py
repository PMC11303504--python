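"""Per-bin B-allele-frequency likelihood curves from het-site allele depths.

Phase is unknown in a typical germline VCF, so a het site with allele depths
(ad_ref, ad_alt) is modelled by a folded binomial: the alt reads came either
from the haplotype at fraction p or from the one at 1-p, and the two cases
are summed. A bin's curve is the (log-space) product of its SNP curves over
a fixed grid p_k = k/(G-1) on [0,1]; it is symmetric about 1/2 by
construction, and the reported maximum-likelihood BAF is folded to [0, 1/2].
Deviations of that maximum from 1/2 are the allelic-imbalance signal the 2D
caller combines with read depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import GridMismatchError, PycnvliteError
from .binned_signals import BinGrid
from .vcf_ingest import VariantRecord

DEFAULT_GRID_SIZE = 101
DEFAULT_MIN_DEPTH = 8


def baf_grid(G: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """The minor-allele-fraction grid p_k = k/(G-1), k = 0..G-1."""
    if G < 3:
        raise PycnvliteError(f"BAF grid needs at least 3 points, got {G}")
    return np.linspace(0.0, 1.0, G)


def _log_binom_matrix(ad_alt: np.ndarray, n: np.ndarray, G: int) -> np.ndarray:
    """log Binom(ad_alt; n, p_k) for every site (rows) and grid point (cols).

    Direct gammaln evaluation; the p=0 and p=1 columns are fixed up exactly
    (pmf is 1 at k=0 resp. k=n, else 0).
    """
    p = baf_grid(G)
    k = ad_alt.astype(float)[:, None]
    nn = n.astype(float)[:, None]
    coeff = gammaln(nn + 1.0) - gammaln(k + 1.0) - gammaln(nn - k + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.log(p)[None, :]
        l1p = np.log1p(-p)[None, :]
        out = coeff + np.where(k > 0, k * lp, 0.0) + np.where(nn - k > 0, (nn - k) * l1p, 0.0)
    out[:, 0] = np.where(ad_alt == 0, 0.0, -np.inf)
    out[:, -1] = np.where(ad_alt == n, 0.0, -np.inf)
    return out


def snp_log_curves(ad_ref: np.ndarray, ad_alt: np.ndarray, G: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Folded-binomial log-likelihood curves for a batch of het sites.

    Row i is log[ Binom(alt_i; n_i, p) + Binom(alt_i; n_i, 1-p) ] up to a
    constant. Because the grid is symmetric, the 1-p term is the column
    reversal of the p term.
    """
    ad_ref = np.asarray(ad_ref, dtype=np.int64)
    ad_alt = np.asarray(ad_alt, dtype=np.int64)
    n = ad_ref + ad_alt
    if np.any(n < 1):
        raise PycnvliteError("site with zero total allele depth")
    L = _log_binom_matrix(ad_alt, n, G)
    return np.logaddexp(L, L[:, ::-1])


def _normalize_log(log_curve: np.ndarray) -> np.ndarray:
    return np.exp(log_curve - logsumexp(log_curve))


def snp_likelihood(ad_ref: int, ad_alt: int, G: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Normalized folded-binomial curve of a single het site."""
    return _normalize_log(snp_log_curves(np.array([ad_ref]), np.array([ad_alt]), G)[0])


def bin_baf_likelihood(
    ad_pairs: Sequence[Tuple[int, int]], G: int = DEFAULT_GRID_SIZE
) -> np.ndarray:
    """Product of per-SNP curves for one bin, computed in log space.

    With one SNP this equals :func:`snp_likelihood`; more SNPs narrow the
    curve. Empty input is a masked bin and is the caller's responsibility.
    """
    if not ad_pairs:
        raise PycnvliteError("bin_baf_likelihood requires at least one het site")
    pairs = np.asarray(ad_pairs, dtype=np.int64)
    logs = snp_log_curves(pairs[:, 0], pairs[:, 1], G)
    return _normalize_log(logs.sum(axis=0))


def max_baf(curve: np.ndarray) -> float:
    """Argmax of a curve folded into [0, 1/2]; exact ties break toward 1/2."""
    curve = np.asarray(curve, dtype=float)
    top = np.max(curve)
    candidates = np.flatnonzero(curve >= top * (1.0 - 1e-12))
    p = candidates / (len(curve) - 1)
    folded = np.minimum(p, 1.0 - p)
    return float(folded[np.argmax(folded)])


def likelihood_overlap(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Bhattacharyya coefficient sum_k sqrt(a_k b_k) of two normalized curves."""
    a = np.asarray(curve_a, dtype=float)
    b = np.asarray(curve_b, dtype=float)
    if a.shape != b.shape:
        raise GridMismatchError(f"curve grids differ: {a.shape} vs {b.shape}")
    return float(min(np.sum(np.sqrt(np.clip(a, 0, None) * np.clip(b, 0, None))), 1.0))


def sigma_from_curve(curve: np.ndarray, floor: float = 0.01) -> float:
    """Gaussian-approximation width of a curve at its peak.

    From the discrete curvature of the log-curve at the argmax:
    sigma = 1/sqrt(-d2 log L / dp2). Boundary peaks or non-concave
    neighborhoods fall back to the floor; the floor also guards against
    overconfident widths from very SNP-rich bins.
    """
    curve = np.asarray(curve, dtype=float)
    G = len(curve)
    dp = 1.0 / (G - 1)
    i = int(np.argmax(curve))
    if i in (0, G - 1):
        # symmetric curve: a boundary peak at G-1 mirrors one at 0
        i = min(i, G - 1 - i) if curve[min(i, G - 1 - i)] >= curve[i] else i
    if 0 < i < G - 1 and curve[i - 1] > 0 and curve[i + 1] > 0:
        lc = np.log(curve[i - 1 : i + 2])
        d2 = (lc[0] - 2 * lc[1] + lc[2]) / dp**2
        if d2 < 0:
            return float(max(1.0 / np.sqrt(-d2), floor))
    return float(floor)


@dataclass
class BAFTrack:
    """Per-bin BAF likelihood curves on a bin grid.

    ``curves[chrom]`` is (n_bins, G) with NaN rows where a bin has no
    usable het site; ``max_baf`` holds the folded argmax per bin and
    ``n_het`` the contributing het-site count (0 <=> masked).
    """

    grid: BinGrid
    G: int
    curves: Dict[str, np.ndarray]
    max_baf: Dict[str, np.ndarray]
    n_het: Dict[str, np.ndarray]
    #: per-bin total allele-depth over contributing het sites; the read
    #: count that sets how fast the folded-likelihood null split shrinks
    het_depth: Dict[str, np.ndarray] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.het_depth is None:
            self.het_depth = {c: np.zeros_like(self.n_het[c]) for c in self.n_het}

    def mask(self, chrom: str) -> np.ndarray:
        return self.n_het[chrom] == 0


def compute_baf_track(
    variants: Iterable[VariantRecord],
    grid: BinGrid,
    G: int = DEFAULT_GRID_SIZE,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> BAFTrack:
    """Build the BAF track from het sites with AD present and depth >= min_depth."""
    per_chrom: Dict[str, List[Tuple[int, int, int]]] = {c: [] for c in grid.chroms}
    for v in variants:
        if not (v.is_het and v.has_ad):
            continue
        n = v.ad_ref + v.ad_alt  # type: ignore[operator]
        if n < max(min_depth, 1):
            continue
        if v.chrom in per_chrom:
            per_chrom[v.chrom].append((grid.bin_index(v.pos), v.ad_ref, v.ad_alt))
    curves, maxb, n_het, het_depth = {}, {}, {}, {}
    for chrom in grid.chroms:
        n_bins = grid.n_bins(chrom)
        mat = np.full((n_bins, G), np.nan)
        mb = np.full(n_bins, np.nan)
        counts = np.zeros(n_bins, dtype=np.int64)
        depths = np.zeros(n_bins, dtype=np.int64)
        sites = per_chrom[chrom]
        if sites:
            arr = np.asarray(sites, dtype=np.int64)
            order = np.argsort(arr[:, 0], kind="stable")
            arr = arr[order]
            logs = snp_log_curves(arr[:, 1], arr[:, 2], G)
            bins, starts = np.unique(arr[:, 0], return_index=True)
            summed = np.add.reduceat(logs, starts, axis=0)
            norm = summed - logsumexp(summed, axis=1, keepdims=True)
            mat[bins] = np.exp(norm)
            counts[bins] = np.diff(np.append(starts, len(arr)))
            site_depth = arr[:, 1] + arr[:, 2]
            depths[bins] = np.add.reduceat(site_depth, starts)
            for b, row in zip(bins, mat[bins]):
                mb[b] = max_baf(row)
        curves[chrom] = mat
        maxb[chrom] = mb
        n_het[chrom] = counts
        het_depth[chrom] = depths
    return BAFTrack(grid=grid, G=G, curves=curves, max_baf=maxb, n_het=n_het,
                    het_depth=het_depth)


def rebin_baf(track: BAFTrack, factor: int) -> BAFTrack:
    """Coarsen by multiplying constituent-bin curves (sum of log curves)."""
    if factor < 1:
        raise PycnvliteError(f"rebin factor must be >= 1, got {factor}")
    if factor == 1:
        return track
    grid = BinGrid(track.grid.contigs, track.grid.bin_size * factor)
    curves, maxb, n_het, het_depth = {}, {}, {}, {}
    tiny = 1e-300
    for chrom in track.grid.chroms:
        fine = track.curves[chrom]
        counts = track.n_het[chrom]
        n_coarse = grid.n_bins(chrom)
        pad = n_coarse * factor - len(counts)
        counts_p = np.pad(counts, (0, pad)).reshape(n_coarse, factor)
        het_depth[chrom] = (
            np.pad(track.het_depth[chrom], (0, pad)).reshape(n_coarse, factor).sum(axis=1)
        )
        logs = np.where(
            np.isfinite(fine), np.log(np.clip(fine, tiny, None)), 0.0
        )
        logs_p = np.pad(logs, ((0, pad), (0, 0))).reshape(n_coarse, factor, track.G)
        summed = logs_p.sum(axis=1)
        cc = counts_p.sum(axis=1)
        mat = np.full((n_coarse, track.G), np.nan)
        mb = np.full(n_coarse, np.nan)
        live = np.flatnonzero(cc > 0)
        if live.size:
            norm = summed[live] - logsumexp(summed[live], axis=1, keepdims=True)
            mat[live] = np.exp(norm)
            for b in live:
                mb[b] = max_baf(mat[b])
        curves[chrom] = mat
        maxb[chrom] = mb
        n_het[chrom] = cc
    return BAFTrack(grid=grid, G=track.G, curves=curves, max_baf=maxb, n_het=n_het,
                    het_depth=het_depth)


def export_baf_tsv(track: BAFTrack, path: Union[str, Path]) -> Path:
    """Write ``chrom  start  end  max_baf  n_het`` (curves live in the store)."""
    rows = []
    size = track.grid.bin_size
    for chrom in track.grid.chroms:
        length = track.grid.contigs[chrom]
        for i in range(len(track.max_baf[chrom])):
            rows.append(
                (chrom, i * size, min((i + 1) * size, length),
                 track.max_baf[chrom][i], int(track.n_het[chrom][i]))
            )
    pd.DataFrame(rows, columns=["chrom", "start", "end", "max_baf", "n_het"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    return Path(path)
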