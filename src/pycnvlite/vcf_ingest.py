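"""Read and write the minimal VCF surface needed for copy-number work.

Copy-number signals can be computed from a whole-genome VCF alone: the
per-sample total read depth (FORMAT/DP) gives a coverage signal and the
allele depths (FORMAT/AD) at heterozygous SNVs give the B-allele frequency.
This module streams exactly that information — one :class:`VariantRecord`
per biallelic SNV — and writes minimal GT:DP:AD VCFs for the simulator.

Coordinate conventions: VCF positions are 1-based; everything downstream
(bins, calls, exports) is 0-based half-open.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple, Union

import pysam

from .errors import ConfigurationError, VcfFormatError

_SNV_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic SNV with the depth information relevant to CN analysis.

    ``ad_ref``/``ad_alt`` are ``None`` when the record carried DP but no AD;
    such records still contribute depth to the RD signal but are excluded
    from BAF. ``dp`` is the caller-reported total depth when present and
    positive, otherwise the AD sum.
    """

    chrom: str
    pos: int  # 1-based
    dp: int
    ad_ref: Optional[int]
    ad_alt: Optional[int]
    is_het: bool

    @property
    def has_ad(self) -> bool:
        return self.ad_ref is not None and self.ad_alt is not None


@dataclass
class ContigMap:
    """Ordered chromosome name -> length (bp) mapping.

    ``inferred`` flags maps reconstructed from record positions because the
    header carried no ##contig lines (lengths are then the max observed pos).
    """

    lengths: Dict[str, int] = field(default_factory=dict)
    inferred: bool = False

    def __post_init__(self) -> None:
        for name, length in self.lengths.items():
            if length <= 0:
                raise VcfFormatError(f"contig {name!r} has non-positive length {length}")

    @property
    def names(self) -> List[str]:
        return list(self.lengths)

    def __contains__(self, name: str) -> bool:
        return name in self.lengths

    def __getitem__(self, name: str) -> int:
        return self.lengths[name]

    def __len__(self) -> int:
        return len(self.lengths)


def _open_vcf(source: Union[str, Path]) -> pysam.VariantFile:
    try:
        return pysam.VariantFile(str(source))
    except (ValueError, OSError) as exc:
        raise VcfFormatError(f"cannot read VCF {source}: {exc}") from exc


def read_contigs(vcf_source: Union[str, Path]) -> ContigMap:
    """Extract the contig map from ##contig header lines.

    Falls back to scanning the records (length := max observed position per
    chromosome, flagged ``inferred``) when the header has no usable contig
    lines. An empty file, or a header-only file without contig lines, is a
    format error.
    """
    vf = _open_vcf(vcf_source)
    lengths: Dict[str, int] = {}
    for name in vf.header.contigs:
        length = vf.header.contigs[name].length
        if length:
            lengths[name] = int(length)
    if lengths:
        return ContigMap(lengths, inferred=False)
    observed: Dict[str, int] = {}
    with vf:
        for rec in vf:
            prev = observed.get(rec.chrom, 0)
            if rec.pos > prev:
                observed[rec.chrom] = rec.pos
    if not observed:
        raise VcfFormatError(
            f"{vcf_source}: no ##contig header lines and no records to infer lengths from"
        )
    return ContigMap(observed, inferred=True)


def _resolve_sample(vf: pysam.VariantFile, sample: Union[str, int, None]) -> str:
    samples = list(vf.header.samples)
    if not samples:
        raise ConfigurationError("VCF has no sample columns")
    if sample is None:
        return samples[0]
    if isinstance(sample, int):
        if not 0 <= sample < len(samples):
            raise ConfigurationError(
                f"sample index {sample} out of range (file has {len(samples)} samples)"
            )
        return samples[sample]
    if sample not in samples:
        raise ConfigurationError(f"sample {sample!r} not in VCF (available: {samples})")
    return sample


def stream_variants(
    vcf_source: Union[str, Path],
    sample: Union[str, int, None] = None,
    counters: Optional[collections.Counter] = None,
) -> Iterator[VariantRecord]:
    """Yield :class:`VariantRecord` for every biallelic SNV of one sample.

    Skipped with a counter entry: multi-allelic sites, indels/MNVs/symbolic
    alleles, records missing both DP and AD, and records whose FORMAT fields
    fail to parse. Heterozygosity is read from GT (0/1 or 1/0, phased or
    not). Records arrive in file order, which for a valid VCF is sorted.
    """
    if counters is None:
        counters = collections.Counter()
    vf = _open_vcf(vcf_source)
    sample_name = _resolve_sample(vf, sample)
    with vf:
        for rec in vf:
            alts = rec.alts
            if alts is None or len(alts) != 1:
                counters["skipped_multiallelic"] += 1
                continue
            ref, alt = rec.ref or "", alts[0] or ""
            if len(ref) != 1 or len(alt) != 1 or ref not in _SNV_BASES or alt not in _SNV_BASES:
                counters["skipped_non_snv"] += 1
                continue
            try:
                fmt = rec.samples[sample_name]
                gt = fmt.get("GT")
                dp = fmt.get("DP")
                ad = fmt.get("AD")
            except (KeyError, ValueError, TypeError):
                counters["skipped_malformed"] += 1
                continue
            ad_ref: Optional[int] = None
            ad_alt: Optional[int] = None
            if ad is not None and len(ad) >= 2 and ad[0] is not None and ad[1] is not None:
                ad_ref, ad_alt = int(ad[0]), int(ad[1])
            if dp is not None and int(dp) > 0:
                depth = int(dp)
            elif ad_ref is not None:
                depth = ad_ref + ad_alt  # type: ignore[operator]
            elif dp is not None:
                depth = int(dp)
            else:
                counters["skipped_no_depth"] += 1
                continue
            alleles = tuple(a for a in (gt or ()) if a is not None)
            is_het = 0 in alleles and 1 in alleles
            yield VariantRecord(rec.chrom, rec.pos, depth, ad_ref, ad_alt, is_het)


def load_variants(
    vcf_source: Union[str, Path], sample: Union[str, int, None] = None
) -> Tuple[List[VariantRecord], collections.Counter]:
    """Materialize :func:`stream_variants` and return (records, skip counters)."""
    counters: collections.Counter = collections.Counter()
    records = list(stream_variants(vcf_source, sample, counters))
    return records, counters


def write_minimal_vcf(
    contigs: ContigMap,
    variants: Iterable[VariantRecord],
    sample_name: str,
    destination: Union[str, Path],
) -> Path:
    """Write a minimal VCF 4.2 with ##contig headers and GT:DP:AD only.

    Input must be sorted: chromosome blocks in contig-map order, positions
    nondecreasing within each block. REF/ALT are written as placeholder A/C
    (depth signals do not depend on the alleles). Round-trips through
    :func:`stream_variants` on (chrom, pos, dp, ad_ref, ad_alt, is_het).
    """
    destination = Path(destination)
    order = {name: i for i, name in enumerate(contigs.names)}
    lines = ["##fileformat=VCFv4.2"]
    for name in contigs.names:
        lines.append(f"##contig=<ID={name},length={contigs[name]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref,alt)">')
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_name}")
    prev: Optional[Tuple[int, int]] = None
    for v in variants:
        if v.chrom not in order:
            raise VcfFormatError(f"variant on unknown contig {v.chrom!r}")
        key = (order[v.chrom], v.pos)
        if prev is not None and key < prev:
            raise VcfFormatError(
                f"variants not sorted: {v.chrom}:{v.pos} after previous block"
            )
        prev = key
        gt = "0/1" if v.is_het else "1/1"
        ad = f"{v.ad_ref},{v.ad_alt}" if v.has_ad else "."
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\tA\tC\t.\tPASS\t.\tGT:DP:AD\t{gt}:{v.dp}:{ad}"
        )
    destination.write_text("\n".join(lines) + "\n")
    return destination
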