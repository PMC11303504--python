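# pycnvlite

Copy-number analysis straight from a whole-genome VCF.

A whole-genome variant file already carries everything needed to profile
copy number: the per-sample total read depth (FORMAT/DP) at every variant
site is a sparse sample of the coverage signal, and the allele depths
(FORMAT/AD) at heterozygous SNVs measure the B-allele frequency (BAF).
`pycnvlite` bins those two signals, segments them, and calls copy-number
variants and alterations — deletions, duplications, and copy-neutral loss
of heterozygosity (CNN-LOH) — with an estimated cell fraction for subclonal
events, without ever touching the (much larger) alignment file.

It is aimed at people analyzing germline or cancer whole-genome data who
want CN profiles, allelic imbalance, and subclone fractions from compact
VCF input, plus a documented HDF5 store of every intermediate signal.

## The model

Read depth is binned (mean DP over the variant sites in each fixed-width
window) and scaled so that the genome-wide median of autosomal bins sits at
copy number 2. Each het site contributes a phase-unknown folded-binomial
likelihood over the minor-allele fraction p:

    L(p) ∝ Binom(ad_alt; n, p) + Binom(ad_alt; n, 1−p),   n = ad_ref + ad_alt

and a bin's BAF curve is the product of its sites' curves on a 101-point
grid, reported as the folded argmax in [0, ½].

Two callers operate on the CN track:

* **RD caller** — CNVnator-style mean-shift segmentation (Gaussian kernels
  in position and signal value, swept over bandwidths 2…128 bins, t-test
  merging), then calls segments whose mean departs from CN 2.
* **2D caller** (default) — agglomerative merging of adjacent bins with
  distance

      d(s,t) = (m_s − m_t)² / (σ² (1/n_s + 1/n_t)) − 2 ln BC(curve_s, curve_t)

  where BC is the Bhattacharyya coefficient of the segments' BAF curves.
  Each segment is then genotyped by jointly fitting its (CN, BAF) to the
  three event models

      deletion:    CN = 2 − f,  BAF = (1−f)/(2−f)
      duplication: CN = 2 + f,  BAF = 1/(2+f)
      cnn-LOH:     CN = 2,      BAF = (1−f)/2

  over the cell fraction f ∈ (0, 1], so a 6% subclonal gain is resolved as
  (CN 2.06, BAF 0.485) — a shift neither signal could call alone.

All signals, likelihood curves, and calls persist in a compressed HDF5
"pytor-style" container at multiple bin sizes (10 kb / 100 kb / 1 Mb by
default). A simulator generates VCF + ground-truth samples for any event
configuration, and a concordance harness compares call sets by reciprocal
overlap. Details: [docs/methods.md](docs/methods.md).

## Worked example

Simulate a 30-Mb tumor-like sample at 30× with a clonal 6-Mb deletion and a
40%-cell-fraction 6-Mb duplication, then ingest and call it:

```console
$ pycnvlite simulate --spec spec.json --out-prefix tumor
$ pycnvlite ingest --vcf tumor.vcf --out tumor.h5 --bins 100000,1000000
INFO pycnvlite: read 29803 variant records (skipped: {})
INFO pycnvlite: stored bin sizes [100000, 1000000] in tumor.h5
$ pycnvlite call --store tumor.h5 --caller 2d --bin 100000 --out calls.tsv
INFO pycnvlite: global depth 30.018 (raw signal), caller=2d bin=100000
INFO pycnvlite: 2 calls written to calls.tsv
$ cat calls.tsv
chrom	start	end	type	cn	cell_fraction	p_adj	caller	bin_size
chr1	5000000	11000000	deletion	1.00139	0.99861	0	2d	100000
chr1	18000000	24000000	duplication	2.40296	0.402958	4.10671e-308	2d	100000
```

Both events are recovered at exact bin resolution: the clonal deletion at
CN 1.00 with cell fraction 1.00, and the subclonal duplication at CN 2.40
with cell fraction 0.40 (truth: 0.40). Comparing against the simulator's
truth table:

```console
$ pycnvlite compare-calls --ref tumor.truth_calls.tsv --query calls.tsv
{
  "n_ref": 2, "n_query": 2,
  "recall": 1.0, "type_concordance": 1.0, "n_matched": 2
}
```

Coordinates in all text outputs are 0-based half-open (BED convention);
VCF positions remain 1-based.

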