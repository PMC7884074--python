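# Methods

`pirna-dimorph` implements the computational side of a germline study of
sexually dimorphic piRNA transcription in *C. elegans*: classifying 21U-RNAs
as male- or female-biased from small RNA-seq counts, quantifying
transcription-factor ChIP signal over 1 kb genome bins with an input-median
exclusion filter and piRNA-5′-anchored binding profiles, measuring the
upstream core (Ruby) motif and its male-specific 5′-cytosine bias, and
scoring co-immunoprecipitation mass-spectrometry interactors from spectral
counts. A synthetic-data generator provides all inputs with known truth, so
every procedure is certified by parameter recovery rather than by fixtures.

## Coordinate and data conventions

All coordinates are 0-based half-open; BED is written unchanged, GFF3 is
converted on ingest, SAM positions are shifted from 1-based. Alignments and
loci move through the package as pandas DataFrames (`chrom, start, end,
strand, weight, n_hits` / `id, chrom, start, end, strand, sex_class`);
single records are validated dataclasses. A read with `n` genomic hits
carries weight `1/n` per hit so its total weight is 1. The exact-match toy
mapper reports all occurrences of a query and its reverse complement in
deterministic order (chromosome, start, `+` before `−`), standing in for
zero-mismatch short-read alignment on the toy genome.

## Sex classification of piRNAs

Reads are length-filtered to 15–30 nt, assigned to loci sense-strand only
(piRNA loci are stranded transcription units and the abundant 22G-RNA
background is antisense), in one of two multi-mapper modes: `overlap_all`
adds a full count for every read-hit/locus overlap, `proportional` splits
each read's unit weight across its hits and, within a hit, equally across
overlapping loci — so total assigned weight plus unassigned weight equals
the number of reads.

Counts are normalized with median-of-ratios size factors. The differential
test is a self-contained negative-binomial Wald procedure (the analysis is
implemented, not delegated): with group means `m_A, m_B` of normalized
counts and an NB dispersion `α` (variance `μ + αμ²`),

    log2FC = log2(m_B / m_A)
    SE     = (1/ln 2) · sqrt(1/(n_A m_A) + α/n_A + 1/(n_B m_B) + α/n_B)

and p is the two-sided normal tail of `log2FC/SE`, BH-adjusted to q. A
pseudocount of 1 normalized unit enters both means only when one of them is
zero. `α` is a single method-of-moments estimate pooled across features
from within-group residuals, floored at 1e-8: with 3 replicates per group a
per-feature moment estimate is so noisy that the Wald statistic becomes
t-like with ~4 degrees of freedom and the test is anticonservative, whereas
the pooled estimate restores normal calibration (measured type-I fraction
at p ≤ 0.05: ~0.05 across null simulations). The pooled estimate assumes a
roughly common dispersion across features, which matches the generator and
is a reasonable first approximation for piRNA counts; `dispersion=` can be
passed to override.

Classification uses the published thresholds, boundaries inclusive:
male if `log2FC ≥ 0.26` (spermatogenesis over oogenesis) and `q ≤ 0.05`,
female if `log2FC ≤ −0.26` and `q ≤ 0.05`, otherwise NE (not enriched).

Note on power evaluation: when a large, one-sided fraction of features is
perturbed, median-of-ratios normalization absorbs part of the shift and
compresses fold changes (its assumption that most features are unchanged is
violated). The packaged power checks therefore plant balanced effects
(equal numbers up in each condition); with one-sided designs the measured
"power" would confound the test with this normalization property.

## ChIP quantification over 1 kb bins

Reads are extended to 200 bp (the average fragment length) in their 3′
direction, clipped at chromosome ends. The genome is tiled with
consecutive, non-overlapping 1 kb bins; each fragment distributes its
weight over the bins it overlaps proportionally to overlapped bp, so raw
coverage sums to the number of fragments (a non-splitting compatibility
mode exists). Coverage is scaled to counts per million, with configured
chromosomes (MtDNA) excluded from the depth.

The exclusion filter drops bins whose IP coverage falls strictly below the
median input coverage of piRNA-depleted bins (zero piRNA 5′ nucleotides) on
the piRNA chromosome. Normalized (not raw) coverage is used on both sides —
both libraries are then on a common scale — with a `--raw-exclusion`-style
alternative available by passing raw tracks. IP/input ratios add a
pseudocount of 1 normalized unit on both sides, bounding ratios on sparse
bins.

Differential bins between genotypes use a fold rule on the ratios
(`enriched: case ≥ fold × control`; `depleted: case ≤ control/fold`;
default fold 2, exposed as a parameter): the source analysis reports bin
counts but not its comparison statistic, so the rule is a package decision
certified against synthetic truth. Eligibility is an explicit bin mask,
taken by the pipeline from the exclusion filter of the *reference (tagged)
IP sample*. Requiring non-exclusion in both samples sounds symmetric but is
degenerate in practice: a control IP with no binding is statistically
uniform, sits at its own input median, and loses ~half of all bins to
Poisson chance, destroying recovery of genuinely bound bins. With a fixed
mask, `enriched(case, control)` and `depleted(control, case)` are the same
set by construction.

Bins are classified by the piRNAs whose 5′ nucleotide they contain
(`all_male` / `all_female` / `all_NE` / `mixed` / `none`); membership by 5′
nt keeps classification consistent with the 5′-anchored profiles. Cluster
specificity is a two-sided rank-sum test of non-excluded bin ratios inside
vs outside the configured cluster intervals. Binding profiles sample a
50 bp-resolution signal track over ±500 bp windows around piRNA 5′
nucleotides, strand-aware (minus-strand windows reversed so upstream is
left), reporting across-anchor mean ± standard error and a heatmap matrix
sorted by descending row mean.

A known bin-boundary effect: 200 bp fragments jittered around a motif near
a bin edge deposit genuine signal into the adjacent bin, so a female-only
bin abutting a male locus can be correctly called enriched. This is a
property of binned quantification, not an error of the caller; analyses
that require class purity should additionally screen flanking bins.

## Core-motif statistics

Upstream windows (60 nt, last base adjacent to the piRNA 5′ nt; minus-strand
windows reverse-complemented) feed an exact k-mer enumeration: for each
8-mer, `n` = number of windows containing ≥ 1 match (one hit per sequence,
ZOOPS-like), per-window hit probability `1 − (1 − q)^(L−k+1)` with `q` the
product of background base frequencies, p the one-sided binomial tail
`P(X ≥ n)`, and `E = p · 4^k`; ties break lexicographically. Enumeration is
complete and deterministic for a fixed-width motif, unlike EM-based suites,
and its E-value is checkable against term-by-term summation — though not
numerically comparable to EM-suite E-values. Background frequencies default
to the supplied window set.

A PWM is built over the leftmost match per window of an exact or IUPAC
pattern (e.g. `NNGTTTCA`), with 0.25/base pseudocounts; offsets place the
motif's first base relative to the piRNA 5′ nt (upstream negative). The 5′-C
bias is the fraction of occurrences with C at motif position 1, tested
two-sided binomial against the background C frequency; the offset summary is
the median and IQR of the position-1 (C) offset. The display consensus uses
the majority base at ≥ 0.5 else an IUPAC class; `cover_pattern()` gives the
IUPAC word covering every observed base, which re-finds all recorded
occurrences on rescanning.

## IP-MS spectral counts

Peptide counts are normalized per sample to fractions of the sample total.
Enrichment is `log2((mean IP fraction + δ)/(mean control fraction + δ))`
with δ defaulting to one peptide in the deepest sample. Significance pools
counts across replicates within arms and tests each protein's 2×2 table
(protein vs rest × IP vs control) with Fisher's exact test, Bonferroni
adjusted over the proteins tested; all-zero proteins are dropped first so
untestable rows do not inflate the correction. The count-based test is a
package decision (exact and assumption-light for spectral counts); the
source analysis states only its adjustment method.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions used throughout the tests.

* **Genome.** One 8 Mb chromosome ("chrIV"), an ~1:2 scale model of the
  real 17.5 Mb chromosome IV, with two piRNA clusters at [1.5, 2.4) Mb and
  [4.6, 6.2) Mb preserving the real small:big proportions. Background base
  composition is uniform (the simplest null for motif E-values).
* **Loci.** 600 male, 300 female, 600 NE Type I loci (~0.6 loci/kb of
  cluster; real clusters are denser, ~2.5/kb) on an evenly spaced slot grid
  with uniform jitter — guaranteeing non-overlap and clean 60 nt upstream
  windows; real inter-locus spacing statistics are not reproduced. Each
  locus is a unique 21-mer starting with T (5′ U) and carries NNGTTTCA
  ending 2 bp (`motif_gap`, configurable) upstream of the 5′ nt; male loci
  draw C at motif position 1 with probability 0.95. An optional
  `dup_fraction` plants exact 21-mer duplicates for multi-mapper tests.
* **Small RNA-seq.** Per-locus counts are negative binomial (dispersion
  0.05) around class-dependent means: base 200, ×2.5 in spermatogenesis for
  male loci, ×2 in oogenesis for female loci; library scales drawn uniform
  [0.7, 1.3]. Reads sit exactly on their locus (sense); 30% of each library
  is background, two thirds 22 nt 5′-G antisense reads over loci and one
  third random 16–30-mers; a constant "U18-like" normalizer feature (mean
  1000) is included. No sequencing-error, adapter or duplicate modelling.
* **ChIP.** Input fragments are uniform; IP fragments mix uniform
  background (70%) with bound fragments (30%) centred on the motif midpoint
  of a locus drawn proportional to occupancy(genotype), Gaussian jitter
  sd 60 bp, fragment length 200 bp, reported as 50 bp 5′-end reads on a
  random strand. Occupancy: `tagged` binds male loci only; `no_tag` and
  `degron` bind nothing (the whole library becomes background). Input depth
  defaults to 5× IP depth: at the desk-scale 200 k-fragment depth the
  criteria prescribe, a 1× input is the dominant noise term of the bin
  ratio, and a deep input isolates the IP-side signal the procedure is
  meant to measure.
* **Peptides.** Control counts are multinomial over a lognormal-jittered
  baseline (σ = 0.5) of 400 proteins; IP counts multiply interactor
  baselines by their enrichment factors and renormalize.

All randomness flows from one `numpy` generator per call, so identical
seeds give byte-identical outputs. What passing recovery tests on this
generator does **not** show: robustness to alignment error, GC or
amplification bias, dispersion heterogeneity across loci, partial degron
depletion, or real locus spacing — the generator's regularities are exactly
the assumptions of the analyses, no more.

## Numerical choices and degenerate inputs

Exact rank-sum enumeration is used up to combined n = 20 without ties;
exact mode refuses ties (midranks + normal approximation with continuity
correction instead). Exact p-values are never floored or clipped for
display. Identical constant samples return p = 1. Fisher's test requires
positive margins; degenerate IP-MS rows are flagged with p = 1. BH is
applied in input order. The NB dispersion floor is 1e-8; all-zero features
are reported untestable (NaN statistics, NE call). Reads longer than the
fragment length pass through extension unchanged with a warning; anchors
whose profile window leaves the chromosome are dropped with a warning.
Profile baselines are the mean over the outer quarter of positions on each
side.

## Problem sizes in the packaged checks

The recovery suite runs the full study conditions (1500 loci, ~0.5 M reads
per small-RNA sample, 200 k IP fragments per genotype with 1 M-fragment
inputs, 2000-feature calibration runs × 10 seeds, 100-seed IP-MS power) in
under two minutes; `scripts/acceptance.py` recomputes the same quantities
from scratch in ~35 s.
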