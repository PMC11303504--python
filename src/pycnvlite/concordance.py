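"""Concordance surfaces: per-bin CN-difference statistics and call matching.

These reproduce, at simulation scale, the two comparisons used to justify
computing copy number from a VCF instead of the alignment: the distribution
of per-bin CN differences between the two depth sources, and the fraction
of calls recovered (recall) plus the agreement of their event types.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .binned_signals import CNTrack
from .callers import CNVCall
from .errors import GridMismatchError


@dataclass
class DiffStats:
    """Summary of per-bin CN differences over jointly unmasked bins."""

    n_bins: int
    mean: float
    sd: float
    q05: float
    q25: float
    q50: float
    q75: float
    q95: float


def rd_difference_stats(cn_a: CNTrack, cn_b: CNTrack) -> DiffStats:
    """Stats of cn_a - cn_b per bin, restricted to bins unmasked in both."""
    if not cn_a.grid.same_as(cn_b.grid):
        raise GridMismatchError("CN tracks are on different grids")
    diffs: List[np.ndarray] = []
    for chrom in cn_a.grid.chroms:
        a, b = cn_a.values[chrom], cn_b.values[chrom]
        both = np.isfinite(a) & np.isfinite(b)
        diffs.append((a - b)[both])
    d = np.concatenate(diffs) if diffs else np.empty(0)
    if d.size == 0:
        return DiffStats(0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
    q = np.percentile(d, [5, 25, 50, 75, 95])
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return DiffStats(int(d.size), float(d.mean()), sd, *map(float, q))


@dataclass
class MatchReport:
    """One-to-one matching of a query call set against a reference set.

    ``recall`` is the fraction of reference calls matched;
    ``type_concordance`` the fraction of matched pairs with equal type
    (``None`` when there are no matches). ``pairs`` holds
    (ref_index, query_index, overlap_bp).
    """

    n_ref: int
    n_query: int
    recall: float
    type_concordance: Optional[float]
    pairs: List[Tuple[int, int, int]]


def match_calls(
    calls_ref: Sequence[CNVCall],
    calls_query: Sequence[CNVCall],
    min_reciprocal_overlap: float = 0.5,
) -> MatchReport:
    """Greedy best-overlap one-to-one matching at a reciprocal threshold.

    A pair qualifies when overlap/len_ref and overlap/len_query are both at
    least the threshold; qualifying pairs are assigned in decreasing overlap
    order (leftmost pair on ties), each call used at most once, so
    fragmented hits count only once and recall never exceeds 1.
    """
    if not 0 < min_reciprocal_overlap <= 1:
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    candidates: List[Tuple[int, int, int, int, int]] = []
    for i, r in enumerate(calls_ref):
        for j, q in enumerate(calls_query):
            if r.chrom != q.chrom:
                continue
            ov = min(r.end, q.end) - max(r.start, q.start)
            if ov <= 0:
                continue
            if ov >= min_reciprocal_overlap * (r.end - r.start) and ov >= min_reciprocal_overlap * (
                q.end - q.start
            ):
                candidates.append((-ov, r.start, q.start, i, j))
    candidates.sort()
    used_ref, used_query = set(), set()
    pairs: List[Tuple[int, int, int]] = []
    for neg_ov, _, _, i, j in candidates:
        if i in used_ref or j in used_query:
            continue
        used_ref.add(i)
        used_query.add(j)
        pairs.append((i, j, -neg_ov))
    n_ref = len(calls_ref)
    recall = len(pairs) / n_ref if n_ref else 1.0
    if pairs:
        agree = sum(1 for i, j, _ in pairs if calls_ref[i].type == calls_query[j].type)
        type_concordance: Optional[float] = agree / len(pairs)
    else:
        type_concordance = None
    return MatchReport(
        n_ref=n_ref,
        n_query=len(calls_query),
        recall=recall,
        type_concordance=type_concordance,
        pairs=pairs,
    )


def report_to_dict(report: MatchReport) -> dict:
    return {
        "n_ref": report.n_ref,
        "n_query": report.n_query,
        "recall": report.recall,
        "type_concordance": report.type_concordance,
        "n_matched": len(report.pairs),
    }


def diffstats_to_dict(stats: DiffStats) -> dict:
    return {k: getattr(stats, k) for k in ("n_bins", "mean", "sd", "q05", "q25", "q50", "q75", "q95")}
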