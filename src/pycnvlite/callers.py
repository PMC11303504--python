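"""CNV/CNA callers: mean-shift RD segmentation and the joint RD+BAF 2D caller.

Two callers operate on the CN-unit track:

* the RD caller partitions each chromosome by mean-shift (Gaussian kernels
  in bin position and signal value, swept over increasing bandwidths, with
  t-test merging of indistinguishable neighbors) and calls segments whose
  mean departs from the diploid level;
* the 2D caller agglomeratively merges adjacent bins whenever both their
  depth levels and their BAF likelihood curves are compatible, then
  genotypes each segment as deletion / duplication / copy-neutral LOH with
  a cell fraction f, the proportion of cells carrying the event.

The three genotype models tie CN and BAF to f:

    deletion     CN = 2 - f,  BAF = (1-f)/(2-f)
    duplication  CN = 2 + f,  BAF = 1/(2+f)
    cnn-LOH      CN = 2,      BAF = (1-f)/2

so a clonal het deletion sits at (1, 0), a clonal single-copy gain at
(3, 1/3), and a 6% subclonal gain at (2.06, 0.485) — resolvable only
because depth and allelic imbalance are fitted jointly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .baf_likelihood import BAFTrack, likelihood_overlap, max_baf, sigma_from_curve
from .binned_signals import CNTrack
from .errors import GridMismatchError, PycnvliteError

logger = logging.getLogger(__name__)

DELETION = "deletion"
DUPLICATION = "duplication"
CNNLOH = "cnnloh"
NEUTRAL = "neutral"


@dataclass
class CallerParams:
    """Tunable thresholds shared by both callers.

    ``d_max`` is the 2D merge stop: the squared normalized depth gap minus
    twice the log Bhattacharyya overlap of the BAF curves must stay below it
    for two adjacent segments to merge. ``neutral_margin`` is the objective
    slack within which the diploid model explains a segment as well as the
    best CNV model.
    """

    bandwidths: Tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128)
    merge_alpha: float = 0.01
    min_cn_shift: float = 0.5
    alpha: float = 0.05
    d_max: float = 9.0
    baf_sigma_floor: float = 0.01
    sigma_baseline: float = 0.01
    min_call_bins: int = 8
    #: width (in minor-allele-fraction units) of the Gaussian applied to
    #: BAF curves before computing merge overlap; one grid step, because
    #: sub-grid overlap precision is an artifact of the discretization
    baf_overlap_smooth: float = 0.01
    #: null BAF-split coefficient: under a diploid null the folded-likelihood
    #: argmax wanders from 1/2 by ~coeff * (total het reads)^(-1/4)
    baf_split_coeff: float = 0.35
    f_grid_step: float = 0.001
    neutral_margin: float = 2.0

    def __post_init__(self) -> None:
        if list(self.bandwidths) != sorted(set(self.bandwidths)) or min(self.bandwidths) < 1:
            raise PycnvliteError("bandwidths must be increasing positive integers")
        for name in ("merge_alpha", "min_cn_shift", "alpha", "d_max", "f_grid_step"):
            if getattr(self, name) <= 0:
                raise PycnvliteError(f"{name} must be positive")


@dataclass
class Segment:
    """A run of bins with homogeneous CN (and, for the 2D caller, BAF)."""

    chrom: str
    bin_start: int
    bin_end: int  # half-open bin indices
    cn_mean: float
    n_bins: int
    max_baf: Optional[float] = None
    baf_curve: Optional[np.ndarray] = None


@dataclass
class CNVCall:
    """A called copy-number event in bp coordinates (0-based half-open)."""

    chrom: str
    start: int
    end: int
    type: str
    cn: float
    cell_fraction: float
    p_value: float
    caller: str
    bin_size: int


def estimate_bin_noise(cn_track: CNTrack) -> float:
    """Difference-based robust per-bin noise of the CN signal.

    1.4826 * median|x[i+1] - x[i]| / sqrt(2) over adjacent unmasked pairs —
    insensitive to a modest number of true CN steps.
    """
    diffs: List[np.ndarray] = []
    n_unmasked = 0
    for chrom in cn_track.grid.chroms:
        x = cn_track.values[chrom]
        finite = np.isfinite(x)
        n_unmasked += int(finite.sum())
        both = finite[:-1] & finite[1:]
        if both.any():
            diffs.append(np.abs(np.diff(x))[both])
    if n_unmasked < 10:
        raise PycnvliteError(f"need >= 10 unmasked bins to estimate noise, have {n_unmasked}")
    if not diffs:
        return 0.0
    return float(1.4826 * np.median(np.concatenate(diffs)) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# mean-shift RD caller
# ---------------------------------------------------------------------------

def _mean_shift_vector(x: np.ndarray, h: int, sigma: float) -> np.ndarray:
    """shift(i) = sum_{0<|j-i|<=3h} (j-i) K_pos(j-i) K_val(x_i, x_j)."""
    n = len(x)
    s = np.zeros(n)
    inv2h2 = 1.0 / (2.0 * h * h)
    inv2s2 = 1.0 / (2.0 * sigma * sigma) if sigma > 0 else None
    for d in range(1, min(3 * h, n - 1) + 1):
        kd = d * np.exp(-d * d * inv2h2)
        if inv2s2 is None:
            e = np.ones(n - d)
        else:
            e = np.exp(-((x[:-d] - x[d:]) ** 2) * inv2s2)
        s[:-d] += kd * e
        s[d:] -= kd * e
    return s


def _ttest_merge(x: np.ndarray, bounds: List[int], alpha: float) -> List[int]:
    """Merge adjacent segments of ``x`` whose two-sample t-test p > alpha.

    ``bounds`` is the sorted list of segment boundaries including 0 and
    len(x); merging removes interior boundaries, largest p first. Degenerate
    pairs (combined n < 3 or zero pooled variance) merge iff the means are
    equal to machine precision — a noiseless step is never merged away.
    """
    def pair_p(a: np.ndarray, b: np.ndarray) -> float:
        if len(a) + len(b) < 3:
            return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        va = a.var(ddof=1) if len(a) > 1 else 0.0
        vb = b.var(ddof=1) if len(b) > 1 else 0.0
        if va + vb == 0.0:
            return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return float(p) if np.isfinite(p) else 1.0

    bounds = sorted(bounds)
    while len(bounds) > 2:
        ps = [
            pair_p(x[bounds[k]: bounds[k + 1]], x[bounds[k + 1]: bounds[k + 2]])
            for k in range(len(bounds) - 2)
        ]
        k = int(np.argmax(ps))
        if ps[k] > alpha:
            del bounds[k + 1]
        else:
            break
    return bounds


def _partition_run(x: np.ndarray, params: CallerParams, sigma: float) -> List[int]:
    """Multi-bandwidth mean-shift partition of one unmasked run; returns bounds."""
    n = len(x)
    if n == 1:
        return [0, 1]
    bounds = [0, n]
    work = x.copy()
    for h in params.bandwidths:
        s = _mean_shift_vector(work, h, sigma)
        new = {i + 1 for i in range(n - 1) if s[i] < 0.0 and s[i + 1] > 0.0}
        bounds = sorted(set(bounds) | new)
        bounds = _ttest_merge(x, bounds, params.merge_alpha)
        for a, b in zip(bounds[:-1], bounds[1:]):
            work[a:b] = x[a:b].mean()
    return bounds


def mean_shift_partition(
    cn_track: CNTrack, params: Optional[CallerParams] = None, sigma: Optional[float] = None
) -> List[Segment]:
    """Segment each chromosome's CN signal by multi-bandwidth mean shift.

    Masked bins split segments: a segment never spans a masked gap. A
    perfectly constant run yields a single segment (all shifts are zero and
    the strict sign-change rule finds no breakpoint).
    """
    params = params or CallerParams()
    if sigma is None:
        sigma = estimate_bin_noise(cn_track)
    segments: List[Segment] = []
    for chrom in cn_track.grid.chroms:
        x = cn_track.values[chrom]
        finite = np.isfinite(x)
        if not finite.any():
            continue
        # contiguous unmasked runs
        idx = np.flatnonzero(finite)
        breaks = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, breaks):
            vals = x[run]
            bounds = _partition_run(vals, params, sigma)
            for a, b in zip(bounds[:-1], bounds[1:]):
                segments.append(
                    Segment(
                        chrom=chrom,
                        bin_start=int(run[a]),
                        bin_end=int(run[b - 1]) + 1,
                        cn_mean=float(vals[a:b].mean()),
                        n_bins=b - a,
                    )
                )
    return segments


def call_rd(
    segments: Sequence[Segment], cn_track: CNTrack, params: Optional[CallerParams] = None
) -> List[CNVCall]:
    """Turn RD segments into deletion/duplication calls.

    A segment is called when its mean departs from CN 2 by more than
    ``min_cn_shift`` and a one-sample t-test of its bins against the global
    mean survives Bonferroni correction across segments. The cell fraction
    assumes a single-copy change: f = |cn - 2| clamped to [0, 1] (higher
    amplifications keep their cn but f saturates at 1). CNN-LOH is invisible
    to depth alone and never emitted here.
    """
    params = params or CallerParams()
    pooled = cn_track.unmasked()
    if pooled.size == 0:
        return []
    global_mean = float(pooled.mean())
    n_seg = max(len(segments), 1)
    size = cn_track.grid.bin_size
    calls: List[CNVCall] = []
    for seg in segments:
        if abs(seg.cn_mean - 2.0) <= params.min_cn_shift:
            continue
        vals = cn_track.values[seg.chrom][seg.bin_start : seg.bin_end]
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2:
            continue
        if vals.var(ddof=1) == 0.0:
            p = 0.0 if not np.isclose(vals.mean(), global_mean) else 1.0
        else:
            _, p = stats.ttest_1samp(vals, popmean=global_mean)
        p_adj = min(float(p) * n_seg, 1.0)
        if p_adj >= params.alpha:
            continue
        calls.append(
            CNVCall(
                chrom=seg.chrom,
                start=seg.bin_start * size,
                end=min(seg.bin_end * size, cn_track.grid.contigs[seg.chrom]),
                type=DELETION if seg.cn_mean < 2.0 else DUPLICATION,
                cn=seg.cn_mean,
                cell_fraction=float(np.clip(abs(seg.cn_mean - 2.0), 0.0, 1.0)),
                p_value=p_adj,
                caller="rd",
                bin_size=size,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# 2D caller
# ---------------------------------------------------------------------------

_TINY = 1e-300


def _smooth_kernel(G: int, width: float) -> Optional[np.ndarray]:
    """Discrete Gaussian (sd ``width`` in p units) for overlap smoothing."""
    step = 1.0 / (G - 1)
    half = max(int(np.ceil(4 * width / step)), 1)
    t = np.arange(-half, half + 1) * step
    k = np.exp(-0.5 * (t / width) ** 2)
    return k / k.sum()


def _smoothed(prob: np.ndarray, kernel: Optional[np.ndarray]) -> np.ndarray:
    if kernel is None:
        return prob
    s = np.convolve(prob, kernel, mode="same")
    return s / s.sum()


def baf_null_sigma(total_het_reads: float, coeff: float = 0.35, floor: float = 0.01) -> float:
    """Null spread of the folded-BAF argmax around 1/2.

    The folded binomial has vanishing Fisher information at p = 1/2, so the
    maximum-likelihood BAF of a diploid segment drifts from 1/2 like
    R^(-1/4) in the total het-site read count R (measured empirically; the
    coefficient covers the simulator's coverage range). Used as a floor on
    sigma_b so null "BAF splits" are not mistaken for allelic imbalance.
    """
    if total_het_reads <= 0:
        return floor
    return float(max(coeff * total_het_reads ** -0.25, floor))


def _merge_distance(
    m_s: float, n_s: float, m_t: float, n_t: float,
    curve_s: np.ndarray, curve_t: np.ndarray, sigma: float,
) -> float:
    if sigma > 0:
        rd_term = (m_s - m_t) ** 2 / (sigma * sigma * (1.0 / n_s + 1.0 / n_t))
    else:
        rd_term = 0.0 if m_s == m_t else np.inf
    bc = likelihood_overlap(curve_s, curve_t)
    baf_term = np.inf if bc <= 0.0 else -2.0 * np.log(bc)
    return float(rd_term + baf_term)


def merge_2d(
    cn_track: CNTrack,
    baf_track: BAFTrack,
    params: Optional[CallerParams] = None,
    sigma: Optional[float] = None,
) -> List[Segment]:
    """Agglomerative joint RD+BAF segmentation of each chromosome.

    Starts from one segment per unmasked bin and repeatedly merges the
    adjacent pair with the smallest distance

        d(s,t) = (m_s - m_t)^2 / (sigma^2 (1/n_s + 1/n_t))
                 - 2 ln BC(curve_s, curve_t)

    until the minimum exceeds ``d_max + 2 ln(bins)`` — the base threshold
    plus the selection inflation of the maximum null distance over the
    boundaries examined (leftmost pair on exact ties). A
    merged segment's curve is the renormalized product of its bins' curves.
    Bins lacking het sites participate with a flat (uninformative) curve.

    A cleanup phase then absorbs segments shorter than ``min_call_bins``
    into their nearest-distance neighbor and resumes merging until stable.
    Rationale: a long segment's product curve becomes arbitrarily narrow,
    so a single bin whose BAF fluctuated a few of its own widths away has
    near-zero overlap with it, gets stranded, and would otherwise split one
    real event into fragments separated by an uncallable sliver.
    """
    params = params or CallerParams()
    if not cn_track.grid.same_as(baf_track.grid):
        raise GridMismatchError("CN and BAF tracks are on different grids")
    if sigma is None:
        sigma = estimate_bin_noise(cn_track)
    G = baf_track.G
    uniform_log = np.zeros(G)
    segments: List[Segment] = []
    for chrom in cn_track.grid.chroms:
        x = cn_track.values[chrom]
        idx = np.flatnonzero(np.isfinite(x))
        k = len(idx)
        if k == 0:
            continue
        m = x[idx].astype(float)
        n = np.ones(k)
        lo = idx.astype(int)
        hi = idx.astype(int) + 1
        curves_chrom = baf_track.curves[chrom]
        logc = np.empty((k, G))
        prob = np.empty((k, G))
        kernel = _smooth_kernel(G, params.baf_overlap_smooth)
        sm = np.empty((k, G))
        for r, b in enumerate(idx):
            row = curves_chrom[b]
            if np.isfinite(row).all():
                logc[r] = np.log(np.clip(row, _TINY, None))
            else:
                logc[r] = uniform_log
            p = np.exp(logc[r] - logc[r].max())
            prob[r] = p / p.sum()
            sm[r] = _smoothed(prob[r], kernel)
        nxt = np.arange(1, k + 1)
        prv = np.arange(-1, k - 1)
        dist = np.full(k, np.inf)
        for r in range(k - 1):
            dist[r] = _merge_distance(m[r], n[r], m[r + 1], n[r + 1], sm[r], sm[r + 1], sigma)
        alive = np.ones(k, dtype=bool)
        # selection-aware stop: the merge examines ~k candidate boundaries,
        # and the max of k null chi-square(1) distances grows like 2 ln k,
        # so the threshold must absorb that inflation or long constant
        # regions retain spurious internal boundaries
        d_stop = params.d_max + 2.0 * np.log(max(k, 2))

        def pair_dist(a: int, b: int) -> float:
            return _merge_distance(m[a], n[a], m[b], n[b], sm[a], sm[b], sigma)

        def merge_pair(r: int) -> None:
            """Merge nxt[r] into r and refresh the two affected distances."""
            t = nxt[r]
            m[r] = (m[r] * n[r] + m[t] * n[t]) / (n[r] + n[t])
            n[r] += n[t]
            logc[r] = logc[r] + logc[t]
            logc[r] -= logc[r].max()
            p = np.exp(logc[r])
            prob[r] = p / p.sum()
            sm[r] = _smoothed(prob[r], kernel)
            hi[r] = hi[t]
            alive[t] = False
            dist[t] = np.inf
            nxt[r] = nxt[t]
            if nxt[r] < k:
                prv[nxt[r]] = r
                dist[r] = pair_dist(r, nxt[r])
            else:
                dist[r] = np.inf
            if prv[r] >= 0:
                dist[prv[r]] = pair_dist(prv[r], r)

        def merge_sweep() -> None:
            while alive.sum() > 1:
                r = int(np.argmin(dist))
                if not np.isfinite(dist[r]) or dist[r] > d_stop:
                    break
                merge_pair(r)

        merge_sweep()
        while alive.sum() > 1:
            short = [
                int(r) for r in np.flatnonzero(alive) if n[r] < params.min_call_bins
            ]
            absorbed = False
            for r in short:
                if not alive[r]:
                    continue
                left = prv[r] if prv[r] >= 0 and alive[prv[r]] else -1
                right = nxt[r] if nxt[r] < k and alive[nxt[r]] else -1
                if left < 0 and right < 0:
                    continue
                if right < 0 or (left >= 0 and pair_dist(left, r) <= pair_dist(r, right)):
                    merge_pair(left)
                else:
                    merge_pair(r)
                absorbed = True
            if not absorbed:
                break
            merge_sweep()
        for r in np.flatnonzero(alive):
            segments.append(
                Segment(
                    chrom=chrom,
                    bin_start=int(lo[r]),
                    bin_end=int(hi[r]),
                    cn_mean=float(m[r]),
                    n_bins=int(n[r]),
                    max_baf=max_baf(prob[r]),
                    baf_curve=prob[r].copy(),
                )
            )
    return segments


# ---------------------------------------------------------------------------
# segment genotyping
# ---------------------------------------------------------------------------

def _model_curves(f: np.ndarray, model: str) -> Tuple[np.ndarray, np.ndarray]:
    if model == DELETION:
        return 2.0 - f, (1.0 - f) / (2.0 - f)
    if model == DUPLICATION:
        return 2.0 + f, 1.0 / (2.0 + f)
    if model == CNNLOH:
        return np.full_like(f, 2.0), (1.0 - f) / 2.0
    raise PycnvliteError(f"unknown model {model!r}")


def genotype_segment(
    cn_mean: float,
    max_baf_value: float,
    sigma_m: float,
    sigma_b: float,
    params: Optional[CallerParams] = None,
) -> Tuple[str, float, float]:
    """Fit (model, cell fraction) to a segment's (CN, BAF) observation.

    Minimizes ((cn - CN_model(f))/sigma_m)^2 + ((baf - BAF_model(f))/sigma_b)^2
    over f in (0, 1] for the three event models (0.001 grid, then bounded
    local refinement; ties prefer the smaller f). Returns
    ``(type, model CN at f, f)``; the neutral answer ``("neutral", 2.0, 0.0)``
    is returned when the best fit collapses to the f->0 boundary or the
    diploid model (CN 2, BAF 1/2) scores within ``neutral_margin`` of it.
    """
    params = params or CallerParams()
    if not cn_mean > 0:
        raise PycnvliteError(f"cn_mean must be positive, got {cn_mean}")
    sigma_m = max(sigma_m, 1e-6)
    sigma_b = max(sigma_b, 1e-6)
    step = params.f_grid_step
    f_grid = np.arange(step, 1.0 + step / 2.0, step)

    def objective(f: np.ndarray, model: str) -> np.ndarray:
        cn_f, baf_f = _model_curves(np.asarray(f, dtype=float), model)
        return ((cn_mean - cn_f) / sigma_m) ** 2 + ((max_baf_value - baf_f) / sigma_b) ** 2

    best: Tuple[float, str, float] = (np.inf, NEUTRAL, 0.0)
    for model in (DELETION, DUPLICATION, CNNLOH):
        obj = objective(f_grid, model)
        j = int(np.argmin(obj))  # first minimum -> smallest f
        lo_b, hi_b = max(step, f_grid[j] - step), min(1.0, f_grid[j] + step)
        res = optimize.minimize_scalar(
            lambda f: float(objective(np.array([f]), model)[0]),
            bounds=(lo_b, hi_b),
            method="bounded",
        )
        f_hat, o_hat = (float(res.x), float(res.fun)) if res.fun <= obj[j] else (
            float(f_grid[j]), float(obj[j])
        )
        if o_hat < best[0] - 1e-12:
            best = (o_hat, model, f_hat)
    neutral_obj = float(
        ((cn_mean - 2.0) / sigma_m) ** 2 + ((max_baf_value - 0.5) / sigma_b) ** 2
    )
    o_best, model, f_hat = best
    if model == NEUTRAL or f_hat <= step or neutral_obj <= o_best + params.neutral_margin:
        return NEUTRAL, 2.0, 0.0
    cn_f, _ = _model_curves(np.array([f_hat]), model)
    return model, float(cn_f[0]), f_hat


def segment_sigmas(
    seg: Segment, sigma: float, baf_track: BAFTrack, params: CallerParams
) -> Tuple[float, float]:
    """Measurement uncertainties of a segment's (cn_mean, max_baf).

    sigma_m combines per-bin noise averaging with the shared baseline
    (depth-calibration) uncertainty; sigma_b takes the curvature width of
    the segment's BAF curve, floored by the null-split scale for its total
    het read count (see :func:`baf_null_sigma`).
    """
    sigma_m = max(float(np.sqrt(sigma**2 / seg.n_bins + params.sigma_baseline**2)), 1e-6)
    het_reads = float(baf_track.het_depth[seg.chrom][seg.bin_start : seg.bin_end].sum())
    sigma_b = max(
        sigma_from_curve(seg.baf_curve, params.baf_sigma_floor),
        baf_null_sigma(het_reads, params.baf_split_coeff, params.baf_sigma_floor),
    )
    return sigma_m, sigma_b


def call_2d(
    cn_track: CNTrack,
    baf_track: Optional[BAFTrack],
    params: Optional[CallerParams] = None,
    sigma: Optional[float] = None,
) -> List[CNVCall]:
    """Joint RD+BAF calling: merge_2d, genotype each segment, test significance.

    Per segment, sigma_m = sqrt(sigma^2/n_bins + sigma_baseline^2) — the
    baseline term is the shared depth-calibration (global median)
    uncertainty, which does not average away with segment length — and
    sigma_b comes from the curvature of the segment's BAF curve (floored).
    Significance is a two-sided chi-square (2 df) test that (cn, baf)
    departs from (2, 1/2), Bonferroni-corrected across the number of
    unmasked bins: the agglomerative merge inspects every bin boundary, so
    the effective number of tests is the bin count, not the final segment
    count. Segments narrower than ``min_call_bins`` are never called:
    merging strands occasional tiny segments precisely at joint RD+BAF
    noise extremes, which is also what the significance statistic measures,
    so short calls are unreliable by construction. Without a BAF track,
    falls back to the RD caller with a warning.
    """
    params = params or CallerParams()
    if baf_track is None:
        logger.warning("no BAF track available; falling back to the RD caller")
        segs = mean_shift_partition(cn_track, params, sigma)
        return call_rd(segs, cn_track, params)
    if sigma is None:
        sigma = estimate_bin_noise(cn_track)
    segments = merge_2d(cn_track, baf_track, params, sigma)
    n_tests = max(int(cn_track.unmasked().size), 1)
    size = cn_track.grid.bin_size
    calls: List[CNVCall] = []
    for seg in segments:
        if seg.n_bins < params.min_call_bins:
            continue
        sigma_m, sigma_b = segment_sigmas(seg, sigma, baf_track, params)
        model, cn_fit, f_hat = genotype_segment(
            seg.cn_mean, seg.max_baf, sigma_m, sigma_b, params
        )
        if model == NEUTRAL:
            continue
        stat = ((seg.cn_mean - 2.0) / sigma_m) ** 2 + ((seg.max_baf - 0.5) / sigma_b) ** 2
        p_adj = min(float(stats.chi2.sf(stat, df=2)) * n_tests, 1.0)
        if p_adj >= params.alpha:
            continue
        calls.append(
            CNVCall(
                chrom=seg.chrom,
                start=seg.bin_start * size,
                end=min(seg.bin_end * size, cn_track.grid.contigs[seg.chrom]),
                type=model,
                cn=cn_fit,
                cell_fraction=f_hat,
                p_value=p_adj,
                caller="2d",
                bin_size=size,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# call-table I/O
# ---------------------------------------------------------------------------

_CALL_COLUMNS = (
    "chrom", "start", "end", "type", "cn", "cell_fraction", "p_adj", "caller", "bin_size"
)

_BED_COLORS = {DELETION: "255,0,0", DUPLICATION: "0,0,255", CNNLOH: "0,160,0"}


def write_calls_tsv(calls: Sequence[CNVCall], path) -> None:
    """TSV export: chrom start end type cn cell_fraction p_adj caller bin_size."""
    import pandas as pd

    rows = [
        (c.chrom, c.start, c.end, c.type, c.cn, c.cell_fraction, c.p_value, c.caller, c.bin_size)
        for c in calls
    ]
    pd.DataFrame(rows, columns=list(_CALL_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_calls_tsv(path) -> List[CNVCall]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        CNVCall(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end), type=str(r.type),
            cn=float(r.cn), cell_fraction=float(r.cell_fraction), p_value=float(r.p_adj),
            caller=str(r.caller), bin_size=int(r.bin_size),
        )
        for r in df.itertuples(index=False)
    ]


def write_calls_bed(calls: Sequence[CNVCall], path) -> None:
    """BED9 export, type-colored (deletion red, duplication blue, cnn-LOH green)."""
    lines = []
    for c in calls:
        name = f"{c.type}_cn{c.cn:.2f}_f{c.cell_fraction:.3f}"
        color = _BED_COLORS.get(c.type, "128,128,128")
        score = int(np.clip(-10.0 * np.log10(max(c.p_value, 1e-100)), 0, 1000))
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{score}\t.\t{c.start}\t{c.end}\t{color}"
        )
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_calls_json(calls: Sequence[CNVCall], path) -> None:
    import json
    from pathlib import Path

    payload = [
        {
            "chrom": c.chrom, "start": c.start, "end": c.end, "type": c.type,
            "cn": c.cn, "cell_fraction": c.cell_fraction, "p_adj": c.p_value,
            "caller": c.caller, "bin_size": c.bin_size,
        }
        for c in calls
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
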