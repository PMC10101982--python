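# nadcapseq

Tools for studying **non-canonical RNA caps** — above all NAD caps — in
eukaryotic transcriptomes. Most mRNAs carry an m7G cap, but a subset carry
NAD (nicotinamide adenine dinucleotide) on their 5′ end. Two questions
drive the analyses here: *which* transcripts are NAD-capped, and *where on
the transcript* the cap sits — is it incorporated as the first transcribed
nucleotide (which requires a templated A in the coding strand) or added
post-transcriptionally?

The package implements two computational pipelines plus the statistics
that connect them:

1. **circNC junction analysis** (`nadcapseq.circnc`). A decapped transcript
   is circularized, fusing its 5′ end to the 3′ polyA tail, and PCR
   products spanning the junction are sequenced. The pipeline merges read
   pairs, keeps reads containing a run of **at least 8 A's**, counts unique
   reads, splits each junction read at its polyA run, and aligns both
   flanks to the reference transcript with an affine-gap semiglobal
   aligner. The cap-addition site is the reference position of the first
   base after the run; the transcript 3′ end is the last base before it;
   the run length bounds the polyA tail. Each called cap site is compared
   with the reference base: an `A` is *adenosine-consistent* (compatible
   with ab initio cap incorporation), anything else is *non-adenosine*
   (post-transcriptional capping). Treatment labels distinguish cap
   classes: Rai1 decapping exposes NAD-capped RNA, MDE exposes m7G-capped
   RNA, so the same machinery maps both and compares their start sites.

2. **Capture-enrichment classification** (`nadcapseq.enrichment`). Gene
   counts from an NAD-capture library are compared to standard RNA-seq in
   biological triplicate: TPM recalculation, median-of-ratios size
   factors, a negative-binomial Wald test (var = μ + αμ²) of the
   capture/control ratio, Benjamini–Hochberg adjustment, and the
   classification rule **log₂FC ≥ 1 and q ≤ 0.01** ("enriched at least
   twofold at q ≤ 0.01") that defines the potentially capped set. A
   one-sided Welch t-test on log TPM asks whether one method reaches
   lower-abundance transcripts than another.

3. **Set-overlap statistics** (`nadcapseq.overlap`). Two capped-transcript
   catalogs are compared against a null that keeps set sizes but
   randomizes gene identities over the quantified universe (10,000
   iterations), alongside the closed-form hypergeometric expectation
   and a chi-squared independence test.

`nadcapseq.simdata` generates synthetic transcriptomes, junction amplicon
read pairs with per-read ground truth, NB count matrices with planted
enrichment, and gene sets with forced overlap, so every stage is testable
at desk scale without external data.

## Worked example

`examples/01_junction_calling.py` simulates 300 circNC read pairs per
transcript at 0.5% substitution error and calls the junctions:

```
g00001 (length 590 nt)
  planted predominant NAD cap site (0-based): 29 (210/300 reads); expected call after A-edge absorption: 29
  called cap site 29 (C -> non_adenosine), 3' end 583, polyA >= 28 nt, support 5 (2%)
  ...
```

The caller recovers the planted cap site exactly; the `non_adenosine`
label says the reference base there is not an A, i.e. the NAD cap cannot
have been incorporated during initiation at that position. When the
reference carries A's at the junction edge they are absorbed into the
maximal polyA run ("A-edge absorption") and reported as ambiguous
alternative sites.

`examples/02_enrichment_classification.py` plants 100 fourfold-enriched
genes among 2,000 and runs the classification:

```
genes tested: 2000 of 2000
classified capped (log2FC >= 1, q <= 0.01): 100
  true planted among them: 100 (sensitivity 1.00, false discoveries 0)
  median log2FC of planted genes: 1.94 (planted 2.0)
capped set lower-abundance than top-200 set: t = -19.4, one-sided p = 2.24e-39
```

`examples/03_overlap_statistics.py` compares two catalogs of 268 and 769
transcripts sharing 63 genes over a 6,000-gene universe:

```
shared fraction of B: 8.19% (exclusive to B: 706)
permutation null: 34.28 +/- 5.38 (analytic 34.35 +/- 5.35)
empirical p (overlap >= observed): 1.00e-04
chi-squared independence: chi2 = 28.7, p = 8.48e-08
```

An observed overlap of 63 sits far above the randomized expectation of
~34 ± 5, yet covers only ~8% of the larger catalog — the two capture
methods agree more than chance but see largely different transcripts.

A thin CLI wraps the same pipelines
(`nadcapseq simulate|circnc|enrich|overlap`); every run writes a JSON
config echo sufficient to reproduce it.

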