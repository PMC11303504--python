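"""Synthetic whole-genome samples for end-to-end testing without downloads.

The generator emits the two inputs the concordance comparison needs:

* a variant list (convertible to a minimal GT:DP:AD VCF): het-SNV positions
  with exponential spacing, per-site depth dp ~ Poisson(coverage*CN/2), and
  allele depths ad_alt ~ Binomial(dp, q) where q is the alt-carrying
  haplotype's read fraction under the local event state;
* an alignment-like truth RD track: per-bin depth with the reduced variance
  of read tiling, Normal(mu, sqrt(mu*read_length/bin_size)) truncated at 0,
  expressed in CN units.

The variance gap between the two — variants sample a bin sparsely, reads
tile it — is precisely what the VCF-vs-alignment comparison measures.
Events (deletion / duplication / cnn-LOH at cell fraction f) shift depth
and allele fractions through the same formulas the caller inverts.
Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .binned_signals import BinGrid, CNTrack
from .callers import CNVCall, CNNLOH, DELETION, DUPLICATION
from .errors import SpecValidationError
from .vcf_ingest import ContigMap, VariantRecord

EVENT_TYPES = (DELETION, DUPLICATION, CNNLOH)


@dataclass(frozen=True)
class CNVEvent:
    """A simulated event: bp interval (0-based half-open), type, cell fraction."""

    chrom: str
    start: int
    end: int
    type: str
    f: float


@dataclass
class SampleSpec:
    """Recipe for one synthetic sample.

    ``snp_spacing`` is the mean gap between *het* sites; an additional
    ``hom_fraction`` of all variant sites are hom-alt (they contribute depth
    but no BAF). ``read_length`` only shapes the truth-RD noise.
    """

    contigs: Dict[str, int]
    coverage: float = 30.0
    snp_spacing: float = 1500.0
    hom_fraction: float = 0.33
    read_length: int = 150
    events: List[CNVEvent] = field(default_factory=list)
    seed: int = 0
    truth_bin_size: int = 10000
    dp_overdispersion: float = 0.0  # extra Poisson variance factor (gamma mixing)
    sample_name: str = "sim"

    def validate(self) -> None:
        problems: List[str] = []
        if self.coverage <= 0:
            problems.append(f"coverage must be positive ({self.coverage})")
        if self.snp_spacing <= 0:
            problems.append("snp_spacing must be positive")
        if not 0 <= self.hom_fraction < 1:
            problems.append("hom_fraction must be in [0, 1)")
        for name, length in self.contigs.items():
            if length <= 0:
                problems.append(f"contig {name} has non-positive length")
        by_chrom: Dict[str, List[CNVEvent]] = {}
        for ev in self.events:
            if ev.type not in EVENT_TYPES:
                problems.append(f"unknown event type {ev.type!r}")
            if not 0 < ev.f <= 1:
                problems.append(f"event {ev} has cell fraction outside (0, 1]")
            if ev.chrom not in self.contigs:
                problems.append(f"event on unknown contig {ev.chrom!r}")
            if ev.end <= ev.start:
                problems.append(f"event {ev} has end <= start")
            by_chrom.setdefault(ev.chrom, []).append(ev)
        for chrom, evs in by_chrom.items():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs[:-1], evs[1:]):
                if b.start < a.end:
                    problems.append(f"overlapping events on {chrom}: {a} / {b}")
        if problems:
            raise SpecValidationError("; ".join(problems))

    def to_json(self, path: Union[str, Path]) -> Path:
        payload = asdict(self)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")
        return Path(path)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "SampleSpec":
        payload = json.loads(Path(path).read_text())
        payload["events"] = [CNVEvent(**e) for e in payload.get("events", [])]
        return cls(**payload)


@dataclass
class TruthSet:
    """Ground truth of a simulation: binned true RD (CN units) and event calls."""

    rd: CNTrack
    calls: List[CNVCall]


def event_state(event_type: str, f: float) -> Tuple[float, float]:
    """(total CN, minor haplotype read fraction) of an event at cell fraction f."""
    if event_type == DELETION:
        return 2.0 - f, (1.0 - f) / (2.0 - f)
    if event_type == DUPLICATION:
        return 2.0 + f, 1.0 / (2.0 + f)
    if event_type == CNNLOH:
        return 2.0, (1.0 - f) / 2.0
    raise SpecValidationError(f"unknown event type {event_type!r}")


def local_state(pos: int, events: Sequence[CNVEvent]) -> Tuple[float, float]:
    """CN state at a 1-based position: (2, 0.5) outside all events."""
    zero_based = pos - 1
    for ev in events:
        if ev.start <= zero_based < ev.end:
            return event_state(ev.type, ev.f)
    return 2.0, 0.5


def _site_positions(rng: np.random.Generator, length: int, gap_mean: float) -> np.ndarray:
    pos: List[np.ndarray] = []
    last = 0.0
    while last < length:
        chunk = rng.exponential(gap_mean, size=max(int(length / gap_mean * 0.25), 64))
        cum = last + np.cumsum(chunk)
        pos.append(cum)
        last = float(cum[-1])
    all_pos = np.concatenate(pos)
    ints = np.unique(all_pos.astype(np.int64) + 1)
    return ints[ints <= length]


def _per_position_state(
    positions: np.ndarray, events: Sequence[CNVEvent]
) -> Tuple[np.ndarray, np.ndarray]:
    cn = np.full(len(positions), 2.0)
    minor = np.full(len(positions), 0.5)
    zero_based = positions - 1
    for ev in events:
        inside = (zero_based >= ev.start) & (zero_based < ev.end)
        c, q = event_state(ev.type, ev.f)
        cn[inside] = c
        minor[inside] = q
    return cn, minor


def _mean_cn_per_bin(length: int, bin_size: int, events: Sequence[CNVEvent]) -> np.ndarray:
    n_bins = -(-length // bin_size)
    edges = np.minimum(np.arange(n_bins + 1) * bin_size, length).astype(float)
    widths = np.diff(edges)
    acc = np.full(n_bins, 2.0) * widths
    for ev in events:
        c, _ = event_state(ev.type, ev.f)
        ov = np.clip(np.minimum(edges[1:], ev.end) - np.maximum(edges[:-1], ev.start), 0, None)
        acc += (c - 2.0) * ov
    return acc / widths


def simulate_sample(spec: SampleSpec) -> Tuple[List[VariantRecord], TruthSet]:
    """Draw one sample: variant records plus its :class:`TruthSet`.

    Fully deterministic for a given spec (all draws come from one seeded
    generator in a fixed chromosome order).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    contigs = ContigMap(dict(spec.contigs))
    gap_mean = spec.snp_spacing * (1.0 - spec.hom_fraction)
    variants: List[VariantRecord] = []
    for chrom in contigs.names:
        length = contigs[chrom]
        events = [e for e in spec.events if e.chrom == chrom]
        positions = _site_positions(rng, length, gap_mean)
        n_sites = len(positions)
        is_hom = rng.random(n_sites) < spec.hom_fraction
        cn, minor = _per_position_state(positions, events)
        lam = spec.coverage * cn / 2.0
        if spec.dp_overdispersion > 0:
            shape = 1.0 / spec.dp_overdispersion
            lam = rng.gamma(shape, lam / shape)
        dp = rng.poisson(lam)
        alt_on_minor = rng.random(n_sites) < 0.5
        q = np.where(alt_on_minor, minor, 1.0 - minor)
        ad_alt = rng.binomial(dp, np.clip(q, 0.0, 1.0))
        ad_alt = np.where(is_hom, dp, ad_alt)
        ad_ref = dp - ad_alt
        for i in range(n_sites):
            variants.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(positions[i]),
                    dp=int(dp[i]),
                    ad_ref=int(ad_ref[i]),
                    ad_alt=int(ad_alt[i]),
                    is_het=not bool(is_hom[i]),
                )
            )
    # alignment-like truth RD, drawn after all variant draws (fixed order)
    grid = BinGrid(contigs, spec.truth_bin_size)
    values: Dict[str, np.ndarray] = {}
    for chrom in contigs.names:
        events = [e for e in spec.events if e.chrom == chrom]
        mean_cn = _mean_cn_per_bin(contigs[chrom], spec.truth_bin_size, events)
        mu = spec.coverage * mean_cn / 2.0
        sd = np.sqrt(mu * spec.read_length / spec.truth_bin_size)
        depth = np.clip(rng.normal(mu, sd), 0.0, None)
        values[chrom] = depth * 2.0 / spec.coverage
    truth_calls = [
        CNVCall(
            chrom=ev.chrom,
            start=ev.start,
            end=ev.end,
            type=ev.type,
            cn=event_state(ev.type, ev.f)[0],
            cell_fraction=ev.f,
            p_value=0.0,
            caller="truth",
            bin_size=spec.truth_bin_size,
        )
        for ev in spec.events
    ]
    return variants, TruthSet(rd=CNTrack(grid=grid, values=values), calls=truth_calls)
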