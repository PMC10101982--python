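# Methods

This note records the models, defaults and numerical choices behind
`nadcapseq`, and what the synthetic-data tests do and do not demonstrate
about real data.

## circNC junction model

A transcript whose non-canonical cap has been removed (leaving a 5′
monophosphate) is circularized, joining the capped 5′ end to the 3′ end of
the polyA tail. PCR across the junction yields an amplicon

```
transcript[fwd_primer .. 3' end]  +  A × L  +  transcript[cap site .. rev_primer]
```

read as a ~2 × 250 nt pair. The analysis assumes the amplicon design keeps
products within paired-end reach (the simulators use compact transcript
geometry for the same reason) and that the polyA tail is the only ≥ 8 nt
A homopolymer in the amplicon; the transcriptome generator therefore caps
internal A/T runs at 6 nt, and real references with internal oligo(A)
would need the filter threshold raised.

### Read merging

`merge_pair` scans every overlap offset between read 1 and the reverse
complement of read 2, scores each as matches − mismatches, rejects
overlaps shorter than `min_overlap` (12) or with mismatch fraction above
`max_mismatch_frac` (0.1), and keeps the best score (ties: longer overlap,
then leftmost). Consensus takes the higher-quality base. This is a
defined, deterministic re-implementation of overlap merging, not a clone
of any particular merging tool.

### polyA filter and orientation

A read passes if it contains a maximal run of ≥ 8 consecutive A's
(`min_len = 8`; the boundary is inclusive). Among multiple qualifying runs
the longest is used, ties leftmost. Orientation-unresolved reads are also
tested as their reverse complement (a ≥ 8 T run) and flipped when that is
the qualifying orientation. Exact-run semantics are used: a substitution
inside the tail splits the run; robustness to that is handled at the
alignment step, not by allowing mismatches in the run.

### Flank alignment

The aligner is affine-gap (gap of length k costs open + k·extend),
global on the query and free at both reference ends, with deterministic
traceback (diagonal over query-gap over reference-gap; leftmost optimal
end). Defaults: match +2, mismatch −3, gap open −5, gap extend −2 —
ordinary short-read alignment weights; nothing downstream is sensitive to
their exact values, only to optimality, which is tested by exhaustive
enumeration. N scores as a mismatch.

`call_junction` splits the read at its polyA run and aligns the post-run
segment (5′ flank) and pre-run segment (3′ flank) to the transcript. Two
deviations from a plain query-global alignment matter for error
robustness, and both default on only inside junction calling:

* the run-adjacent end of each flank may be soft-clipped at zero cost
  (`free_query_start` for the 5′ flank, `free_query_end` for the 3′).
  A substitution inside the tail splits the A run and leaves an A remnant
  attached to one flank; without clipping that remnant drags the boundary
  off the true site.
* **tail-first boundary attribution**: aligned columns at the junction
  edge where the read base and the reference base are both A cannot be
  distinguished from tail bases, so they are assigned to the tail — the
  cap site is the first non-(A=A) aligned reference base, and likewise
  mirrored for the 3′ end. Up to 3 upstream reference positions that
  continue in A are reported as ambiguous alternative cap sites, because
  a templated A at the junction is genuinely unresolvable from sequence.

A flank qualifies when it has ≥ `min_flank` (15) aligned bases at
≥ `min_identity` (0.9); confidence is `high` with both flanks, `low` with
one (the qualifying site is still reported), `none` otherwise. The
reported polyA length is a lower bound (the observed run can be truncated
by the read end or shortened by in-tail errors). Read 1, read 2 and the
merged reads are processed as three separate streams; per-gene summaries
prefer the merged stream when nonempty. Support fractions use
junction-spanning (polyA-passing) reads of the same stream as the
denominator. Coordinates are 0-based half-open internally and 1-based
inclusive in reports.

Under these rules, error-free simulated reads are recovered exactly
(site and tail-length expectations adjusted for junction-edge A
absorption recorded in the simulation truth), and at 1% substitution
error ~97% of high-confidence calls still hit the cap site exactly; the
residual misses come from substitutions in the first one or two flank
bases, where clipping is indistinguishable from a shifted boundary.

## Capture-enrichment model

Counts are assumed NB-distributed, var = μ + α·μ², with condition means
compared between one capture condition (nadcappro or spaac) and standard
RNA-seq; minus-ADPRC background columns are carried descriptively and
never enter the test. Stages:

* **TPM**: TPM_i = 10⁶ (c_i/L_i) / Σ_j (c_j/L_j), from rounded counts.
* **Size factors**: median-of-ratios over genes expressed in every
  sample, rescaled to geometric mean 1. Undefined when no gene is
  expressed everywhere.
* **Independent filtering**: genes with total count < 10 across samples
  are excluded before testing (not part of the published rule; documented
  here as this package's choice).
* **Wald test**: β = log((ȳ_t + ½)/(ȳ_c + ½)) on size-factor-normalized
  means, Var(β) = Σ_cond (1/(μ̂+½) + α)/n by the delta method.
  Dispersion modes:
  * `common` (default): one α shared across genes, the **mean** of
    unfloored per-gene method-of-moments estimates over tested genes.
    The mean is used rather than the median because E[s²] = μ + αμ²
    makes the average nearly unbiased, while the median of the
    right-skewed 2-df MoM distribution sits low and inflates type-I
    error. With α treated as known, β/SE is referred to the normal.
  * `per_gene_mom`: α estimated from the gene's own replicates (floored
    at 10⁻⁸); because the variance is then estimated from the same few
    observations, the statistic is referred to a t distribution on
    n_t + n_c − 2 df. With triplicates this mode is necessarily much less
    powerful and is provided for sensitivity analysis, not as the default.
* **BH adjustment** and the inclusive rule log₂FC ≥ 1 AND q ≤ 0.01.
  "q-value" means the BH step-up adjusted p. The fold-change threshold is
  applied to the unshrunken estimate; no shrinkage is implemented.

This is a functional stand-in for a DESeq2-style analysis — the
scientific content is the classification rule and its operating
characteristics, not any particular estimator's internals. At the
simulated study conditions (2,000 genes, triplicates, α = 0.05, depth
10⁶, 100 genes planted at log₂FC = 2) the default mode attains
sensitivity ≈ 1.0 among well-expressed planted genes with empirical
FDR ≈ 0 at q ≤ 0.01, and null matrices give a p ≤ 0.05 fraction of
≈ 0.050–0.054. Calibration is approximate: the shared-dispersion estimate
is itself random, so per-dataset rejection fractions vary slightly more
than binomial sampling alone would predict.

The abundance comparison (`compare_abundance`) is a one-sided Welch
t-test on log(TPM + 1), alternative "set A lower than set B".

## Overlap null

The permutation null redraws |A| and |B| gene identities independently
and uniformly without replacement from the universe each iteration
(default 10,000) and recomputes the intersection. The empirical p uses the
add-one convention (1 + #{perm ≥ obs})/(n_iter + 1), so it is never 0.
The analytic counterpart is hypergeometric: mean n₁n₂/N, variance
n₁n₂(N−n₁)(N−n₂)/(N²(N−1)). The chi-squared independence test is Pearson
without continuity correction (correction available by flag) on the 2×2
membership table. The universe should be the set of quantified genes;
it is always supplied explicitly, never inferred.

## Synthetic data

`generate_transcriptome` draws segment lengths uniformly (defaults:
5′UTR 20–100, CDS 300–900, 3′UTR 50–300 nt), sequences iid with internal
A/T runs capped at 6, NAD and m7G cap-site distributions over the 5′UTR
(three sites, Dirichlet weights, distinct predominant sites), cleavage
sites in the final 10 nt, and primers flanking the CDS. polyA lengths are
truncated normal (mean 30, sd 6, min 12 — the minimum sits above the 8-A
filter so every planted junction is detectable); tail-length and
start-site heterogeneity are plausible placeholders, not estimates of any
real distribution. Substitution errors are uniform; no indels, no PCR
duplicates, no instrument quality profiles. Truth tables record the A
extensions flanking each planted junction so boundary-attribution tests
can be exact, and flag amplicons too long for their read pair.

`simulate_counts` plants an enriched subset at a fixed log₂ fold change
on top of log-normal relative expression rescaled to the library depth,
with NB noise (Poisson when α = 0) in biological triplicate per condition.

Passing tests on these simulations show the *operations* are correct
(boundary arithmetic, optimality, calibration against the model they
assume); they do not show robustness to real-data features the generators
omit — indels, adapter read-through, variable tail composition (e.g.
non-A residues in tails), overdispersion heterogeneity across genes, or
misannotated references.

## Problem sizes

The test suite and the acceptance script use: 5 transcripts × 1,000 read
pairs per junction-recovery condition (compact geometry: 5′UTR 20–60,
CDS 300–500, 3′UTR 50–150 nt, matching an amplicon design whose products
stay within 2 × 250 nt paired-end reach); the full exhaustive sweep of
all 260,100 query/reference pairs of length ≤ 8 over {A, C} for aligner
optimality; 10,000 permutation iterations at the published catalog sizes
(N = 6,000, 268 vs 769); and 10 + 20 seeds of 2,000-gene count matrices
for power and calibration. These sizes give stable statistics while
keeping a full run to a few minutes on one CPU.
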