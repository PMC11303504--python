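"""Reproducible VCF-vs-alignment concordance experiments.

Each experiment simulates a sample, writes its minimal VCF, re-ingests it
through the same path a user's VCF would take, and compares the VCF-derived
copy-number signal or call set against the alignment-like truth produced by
the simulator. They back both the test suite and the reproduction script.
"""

from __future__ import annotations

import tempfile
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .baf_likelihood import BAFTrack, compute_baf_track
from .binned_signals import BinGrid, CNTrack, bin_read_depth, global_depth, to_copy_number
from .callers import (
    CallerParams,
    CNVCall,
    call_2d,
    estimate_bin_noise,
    genotype_segment,
    merge_2d,
    segment_sigmas,
)
from .concordance import DiffStats, MatchReport, match_calls, rd_difference_stats
from .simulate import CNVEvent, SampleSpec, TruthSet, simulate_sample
from .vcf_ingest import ContigMap, load_variants, write_minimal_vcf

_EVENT_CYCLE = ("deletion", "duplication", "cnnloh")


def ingest_simulated(
    spec: SampleSpec, bin_size: int
) -> Tuple[CNTrack, BAFTrack, TruthSet]:
    """Simulate, round-trip through a minimal VCF, and bin the signals.

    Returns the VCF-derived CN track, the BAF track, and the simulator's
    truth set (its RD track is on ``spec.truth_bin_size``).
    """
    variants, truth = simulate_sample(spec)
    contigs = ContigMap(dict(spec.contigs))
    with tempfile.TemporaryDirectory() as tmp:
        vcf_path = Path(tmp) / "sample.vcf"
        write_minimal_vcf(contigs, variants, spec.sample_name, vcf_path)
        reread, _ = load_variants(vcf_path)
    grid = BinGrid(contigs, bin_size)
    rd = bin_read_depth(reread, grid)
    cn = to_copy_number(rd, global_depth(rd))
    baf = compute_baf_track(reread, grid)
    return cn, baf, truth


def neutral_cn_difference(
    seed: int,
    chrom_length: int = 50_000_000,
    coverage: float = 30.0,
    snp_spacing: float = 1500.0,
    bin_size: int = 10_000,
) -> DiffStats:
    """Per-bin CN-difference stats on a neutral (diploid) simulated sample."""
    spec = SampleSpec(
        contigs={"chr1": chrom_length},
        coverage=coverage,
        snp_spacing=snp_spacing,
        seed=seed,
        truth_bin_size=bin_size,
    )
    cn_vcf, _, truth = ingest_simulated(spec, bin_size)
    return rd_difference_stats(cn_vcf, truth.rd)


def clonal_event_layout(
    rng: np.random.Generator,
    chrom: str = "chr1",
    chrom_length: int = 100_000_000,
    n_events: int = 10,
    min_length: float = 1e6,
    max_length: float = 9.5e6,
) -> List[CNVEvent]:
    """Place non-overlapping clonal events, one per equal-width slot.

    Types cycle deletion/duplication/cnnloh so the genome keeps a majority
    of copy-number-2 sequence, which the median depth baseline needs.
    """
    slot = chrom_length // n_events
    events = []
    for i in range(n_events):
        length = rng.uniform(min_length, min(max_length, slot - 4e5))
        start = i * slot + rng.uniform(0, slot - length - 3e5) + 1e5
        events.append(
            CNVEvent(chrom, int(start), int(start + length), _EVENT_CYCLE[i % 3], 1.0)
        )
    return events


def vcf_vs_truth_calls(
    seed: int,
    chrom_length: int = 100_000_000,
    coverage: float = 30.0,
    bin_size: int = 100_000,
    n_events: int = 10,
    min_reciprocal_overlap: float = 0.5,
    params: Optional[CallerParams] = None,
) -> Tuple[MatchReport, List[CNVCall], List[CNVCall]]:
    """Call one simulated sample twice — VCF RD vs truth RD, shared BAF.

    Returns (match report with truth-RD calls as reference, the reference
    calls, the VCF-derived calls).
    """
    rng = np.random.default_rng(seed)
    events = clonal_event_layout(rng, chrom_length=chrom_length, n_events=n_events)
    spec = SampleSpec(
        contigs={"chr1": chrom_length},
        coverage=coverage,
        seed=seed,
        events=events,
        truth_bin_size=bin_size,
    )
    cn_vcf, baf, truth = ingest_simulated(spec, bin_size)
    calls_vcf = call_2d(cn_vcf, baf, params)
    calls_truth = call_2d(truth.rd, baf, params)
    report = match_calls(calls_truth, calls_vcf, min_reciprocal_overlap)
    return report, calls_truth, calls_vcf


def subclone_recovery(
    seed: int,
    cell_fraction: float = 0.06,
    coverage: float = 80.0,
    chrom_length: int = 40_000_000,
    event_span: Tuple[int, int] = (10_000_000, 20_000_000),
    bin_size: int = 100_000,
    params: Optional[CallerParams] = None,
) -> float:
    """Recover the cell fraction of one subclonal duplication.

    Simulates the event, segments jointly on RD+BAF, genotypes the segment
    best overlapping the true event, and returns the fitted f.
    """
    params = params or CallerParams()
    event = CNVEvent("chr1", event_span[0], event_span[1], "duplication", cell_fraction)
    spec = SampleSpec(
        contigs={"chr1": chrom_length},
        coverage=coverage,
        seed=seed,
        events=[event],
        truth_bin_size=bin_size,
    )
    cn_vcf, baf, _ = ingest_simulated(spec, bin_size)
    sigma = estimate_bin_noise(cn_vcf)
    segments = merge_2d(cn_vcf, baf, params, sigma)
    best = max(
        segments,
        key=lambda s: min(s.bin_end * bin_size, event.end)
        - max(s.bin_start * bin_size, event.start),
    )
    sigma_m, sigma_b = segment_sigmas(best, sigma, baf, params)
    _, _, f_hat = genotype_segment(best.cn_mean, best.max_baf, sigma_m, sigma_b, params)
    return f_hat
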