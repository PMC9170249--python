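# Methods

## Scope and model

`methylchrom` analyses the joint behaviour of DNA methylation and
repressive chromatin in a two-genotype (control vs conditional knockout
of a de-novo DNA methyltransferase), three-stage (fetal, newborn, adult)
neuronal study design with two biological replicates per condition.  All
analyses operate on plain-text substrates: allc-style per-cytosine count
tables (chrom, 0-based position, strand, context, methylated calls `m`,
total calls `h`), bedGraph bin-count tracks, BED interval sets and TSV
count matrices.  Coordinates are 0-based half-open throughout; 1-based
inputs are converted at the I/O boundary.

## Methylation quantification

Levels are always pooled-count ratios `100·Σm/ΣH` over the sites in
scope, never means of per-site levels, so deeply covered sites carry
proportionally more weight.  Incomplete bisulfite conversion inflates
apparent methylation: a fraction `ncr` of unmethylated cytosines reads
out methylated.  Levels are corrected by inverting that mixture,
`%mC_adj = 100·(%mC − %NCR)/(100 − %NCR)` clipped to [0, 100]; the
correction is the identity at NCR 0 and maps levels at or below the NCR
to 0.  Zero-coverage sites and bins propagate as missing, never as 0%,
to avoid deflating region levels.  Per-site methylation calls use the
exact binomial upper tail against Binomial(h, ncr), BH-corrected per
sample across all covered sites of the tested context (FDR 0.01).

## DMR calling

Replicate counts are pooled within groups; each CG site covered in both
groups receives a two-sided Fisher exact test (minimum-likelihood
convention) on methylated vs unmethylated calls, BH-corrected across all
tested sites.  Significant same-direction sites at most 500 bp apart
chain into candidate regions; candidates need at least three member
sites.  Region levels are pooled over every tested site in the span; the
region q is the minimum member-site q (a conservative choice — the
combined Stouffer p is recorded alongside for comparison), and retained
regions must satisfy |Δ| ≥ 30 percentage points of mCG and q < 0.01.
Regions where the knockout *gained* methylation can be dropped by flag,
which is the default for the adult-stage comparison where such gains are
attributed to technical noise.

The per-site statistic stands in for the permutation root-mean-square
test of the original methylome tooling, which is not publicly specified;
an exact test is reproducible and oracle-checkable, and the calling
cascade is validated end-to-end by planted-feature recovery instead of
output parity.

## UMR / LMR segmentation and methylation valleys

Low-methylation segmentation is a deterministic re-implementation of the
HMM-based segmenters used in the field, keeping their published
parameters (level cutoff m = 0.3 for adult, 0.5 for newborn samples;
n = 7 sites): maximal runs of consecutive covered CG sites with adjusted
level ≤ 100·m, where runs break at any covered higher site.  Adjacent
runs at most 500 bp apart merge only if the merged span still satisfies
the cutoff as a pooled region; this bridges an isolated noisy site
inside a low region (the role the HMM's smoothing plays) but can never
bridge a genuinely methylated stretch — alternating low/high sites yield
no segment.  Segments with ≥ 30 low sites are UMRs, smaller ones LMRs.
Valleys (DMVs) are UMRs of length ≥ 5 kb with pooled mean mCG ≤ 15%; an
optional PMD mask removes valleys in partially methylated domains.

Valleys called in two conditions are compared pairwise by largest
overlap: identical intervals (within a configurable boundary slack,
default 0 — the literal reading of "exact same") are consistent;
containment is expanded (wider in cKO) or shrunken (wider in control);
partial overlap is overhang; no overlap is condition-unique.  The
overhang category is defined here as partial overlap with neither
containment — the six categories are mutually exclusive and exhaustive,
verified against a brute-force per-base decision table.  For display,
valleys are sorted lexicographically on: differential-H3K27me3 overlap,
up-/down-regulated DE-gene overlap (|log2FC| > 0.2), per-condition
mean-mCG flags (> 30%), presence of contained genes, then mean chromatin
signal; valleys with no contained gene have missing mean logFC and sort
after defined values at equal keys.

## ChIP islands and differential binding

Fragments are assigned to fixed 200-bp bins by midpoint (count is
conserved).  A bin is eligible when its treatment count beats the
Poisson upper tail at λ = library-ratio-scaled control, with the control
rate floored at the genome-wide control mean so sparse control bins do
not create spurious eligibility; a zero-library control falls back to a
flat background estimated from the treatment.  Eligible bins chain into
islands tolerating ≤ 3 consecutive gap bins for the broad mark (≤ 1 for
sharp marks); the island score is the summed −log10 bin p over eligible
members.  Island significance is the Poisson tail of the island's total
count against its summed rate; because bin-level pre-selection biases
these p-values, BH correction uses the total number of genome bins as
the effective test count.  This is deliberately conservative: on pure
noise tracks essentially no islands survive, and at the planted
signal-to-noise (≥ 4×) islands are recovered with per-peak Jaccard ≈ 1.

Differential regions over a peak universe use median-of-ratios size
factors, a common NB dispersion estimated by trimmed method-of-moments
across regions (per-region two-replicate estimates are far too noisy
individually; clipping them at zero before averaging would bias the
common value upward, so trimming is symmetric and only the pooled
estimate is clipped), and a per-region Wald test on the difference of
log group means with delta-method variance `(1/μ + φ)/r`.  BH at FDR
0.05.  Per-region fold-enrichment is RPKM(mark)/RPKM(IgG) with a
0.5-fragment pseudocount on both numerators; metaprofiles average
fold-enrichment in offset bins around region midpoints with a bootstrap
CI across regions.

Peaks are grouped by overlap with differential sets — genotype
differences take precedence over developmental ones when both apply
(conflicts are counted and reported).  CGI-promoter classes follow the
standard rule: a promoter (TSS ± 2 kb) overlapping a CpG island is
bivalent if it overlaps both H3K4me3 and H3K27me3 peaks, active if
H3K4me3 only, other if neither or H3K27me3 only.

## Region enrichment

Enrichment of a query set in a feature is computed on CG-site counts,
not base or region counts: each registered CG dinucleotide is classified
once by (in query?, in feature?), which respects the non-uniform CG
distribution and avoids double-counting regions straddling feature
boundaries.  The association is summarised as
`log2OR = log2(n11·n22/(n12·n21))` with Woolf standard error
`sqrt(1/n11 + 1/n12 + 1/n21 + 1/n22)/ln 2` and a ±2·SE interval; zero
cells receive the Haldane–Anscombe +0.5 on all four cells for the OR and
SE only (flagged in the output) while the Fisher exact p always uses the
raw table, two-sided.  Across many features, BH-corrected q-values are
reported.

Positional association uses permutation: the query set is re-placed
uniformly at random (each region independently, sizes preserved,
placements uniform over every start at which the region fits inside one
allowed segment after include/exclude masking; optional rejection
against overlaps), and the count of query regions with ≥ 1 bp reference
overlap is standardised against the permutation null, with the +1
empirical-p correction.  The local z-curve shifts all query regions by
fixed offsets (default window ± 5 kb, step 50 bp) and re-standardises
against the same null; a sharp peak at offset 0 indicates an association
tied to the exact positions, and a planted displacement moves the peak
accordingly.

## Expression and integration

Genes are kept when CPM > 2 in at least two samples.  Scale factors are
trimmed means of per-gene log2 ratios against a reference sample (30%
trim on M values, 5% on abundance), normalised to geometric mean 1.
Differential expression equalises counts to a common effective library
size, estimates NB dispersions by method of moments with shrinkage
toward the trimmed common value (prior weight 20), and applies an exact
conditional test: given the grand total, the split between group totals
is negative-hypergeometric and independent of the mean; the two-sided p
sums outcomes no more likely than the observed split.  Status up/down
requires q < 0.05 and |FC| > 1.2.

Gene-body levels are pooled counts over [TSS, TES) regardless of strand;
flank profiles orient offsets by strand and average per-gene bin levels
with a normal-approximation CI across genes.  The decile curve ranks
genes by gene-body Δ-mC (ties broken by stable gene-id order), splits
them into ten bins whose sizes differ by at most one (larger bins
first), and reports mean ± SEM expression log2FC per bin.  Explainable
variance compares the squared Pearson correlation of Δ-mC with the
pooled fold-change against the squared correlation between the two
replicate-pair fold-change estimates (the reproducible ceiling).
Expression-matched control genes are drawn by logistic-propensity
nearest-neighbour matching on log(TPM+1), 1:1 without replacement in
descending target-propensity order, rejecting the match (with the
achieved value reported) when the matched-distance SD exceeds 0.01.

## The synthetic-data generator

The generator is first-class, tested code.  It emulates the study design
so that every planted effect is recoverable by the corresponding
analysis stage:

* **Genome** (default 2 chromosomes × 1 Mb): CG dinucleotides as a
  Poisson process with 100 bp mean spacing, registered once per
  dinucleotide (strand-collapsed, so each entry accumulates basecalls
  from both strands and carries twice the per-strand genome coverage);
  CH sites uniform at 0.4 per bp with random strand.
* **Stage targets** (percent, genome-wide weighted): mCG 71/71 (fetal),
  73.1/73.1 (newborn), 72.6/60.1 (adult control/cKO); mCH 0.02, 0.05,
  and 1.98 (control) vs 0.05 (cKO) at the adult stage.  The free
  background level and the mean knockout deficit are solved analytically
  so the site-average equals these targets exactly in expectation given
  every planted override — generator calibration is therefore a
  round-trip test of the quantification operations.
* **Spatial structure**: a per-10-kb gamma "severity" field (shape 4,
  clipped to [0.25, 1.6], mean-normalised) scales local mCH and — damped
  to 15% amplitude — the knockout's background mCG deficit.  The damping
  reflects the near-uniformity of the background loss across genomic
  compartments and keeps unplanted background deficits (≈ 11–14 points)
  well below planted effect sizes (≥ 25 points), so planted truth is
  unambiguous for recovery metrics.  Control-adult mCH is additionally
  elevated (weight 1 + 0.05 × planted loss, capped) at regions of
  planted knockout mCG loss, reflecting that regions dependent on
  de-novo methylation accumulate both marks; this produces the positive
  bin-level correlation between ΔmCG and ΔmCH (≈ 0.4–0.5 at desk scale;
  the full-scale study reports ≈ 0.8).
* **Planted features**, mutually disjoint with 1 kb margins and away
  from chromosome edges: 60 DMRs (1–2 kb; fetal level U[20, 35], adult
  developmental gain U[35, 55] blocked in the knockout), 12 valleys
  (6–10 kb at 8% mCG in both genotypes, 4 widened by 2 kb per side in
  the adult knockout), 43 H3K27me3 peaks on the bin grid (2–5 kb, 6×
  enrichment; groups: stable, fetal-only, adult-only, and 12 "cKO-gain"
  peaks carrying their own planted extra mCG loss U[25, 40]), and 120
  genes (3–6 kb).  DMRs and peaks are only placed where the internal
  CG-site gap is ≤ 400 bp, so planted truth is recoverable under the
  500-bp chaining rule; CG-sparse stretches would otherwise legitimately
  split called regions.
* **Counts**: coverage per site is negative binomial (mean 30 per
  strand, size 8; CG dinucleotides get the two-strand sum), observed
  methylated calls are Binomial(h, p·(1−ncr)+ncr) with ncr 0.005.
  Per-site CG levels add a shared N(0, 8) site effect (clipped), shared
  across genotypes and stages so that between-group differences at
  background sites are pure mean shifts; per-site CH levels carry a
  shared Gamma(2) multiplier.  Replicates share all per-site truth and
  differ only in count sampling.
* **ChIP tracks**: Poisson bin counts at 10 fragments/bin background;
  at the adult stage the knockout's per-peak enrichment is multiplied by
  `2^(coupling × excess mCG loss)` with coupling −0.04 per percentage
  point, where the excess is the peak's mCG change beyond the
  genome-wide background delta — so H3K27me3 fold-changes anti-correlate
  with mCG changes across peaks, strongly at the loss-carrying peaks and
  near-zero elsewhere.  IgG tracks are background only.
* **Expression**: adult-stage counts for both genotypes, two replicates;
  log2 knockout mean = control mean + β × (gene-body ΔmCH in percentage
  points) with β = −0.15, plus planted DE effects (8% of genes at
  |log2FC| = 1).  Counts are NB with dispersion 0.01 (biological
  coefficient of variation 0.1, the conventional value for inbred-mouse
  RNA-seq replicates; at 2+2 replicates and these depths this is also
  the regime in which a fair exact test has usable power).  Library
  depths vary lognormally (σ = 0.1).

Determinism: a run is a pure function of (seed, config); all random
streams are keyed off the seed with fixed per-stage constants, and
re-running any stage from the emitted files reproduces byte-identical
outputs.

### What the generator does not emulate

Sequence composition (no real CpG islands, repeats or SNPs), read-level
artifacts (mapping bias, M-bias, PCR duplicates), sub-context structure
within CH, PMDs, chromosome-scale domain organisation, and H3K4me3 /
H3K27ac tracks (promoter classification is exercised with constructed
interval fixtures).  Passing recovery tests therefore demonstrate the
correctness and calibration of the statistical machinery under the
declared generative model, not robustness to alignment-level artifacts
of real libraries.

## Problem sizes and numerical choices

Default analyses run on a 2 Mb genome at 30× coverage (≈ 20k CG
dinucleotides, ≈ 800k CH sites, 12 methylome samples), which keeps a
full simulate-and-analyse cycle around ten seconds and the entire test
suite under two minutes on one core; unit tests use a 400 kb
configuration.  The decile-curve sign test asserts a strong monotone
trend (Spearman of bin index vs bin mean ≤ −0.5 and last < first decile)
rather than strict bin-by-bin monotonicity: at 120 genes the bin-mean
standard errors exceed adjacent-bin steps, and the planted DE genes
(±1 log2, independent of methylation) add scatter, so literal
monotonicity across ten bins is not statistically attainable at this
scale — at the full-study gene count it would be.  Fisher two-sided
p-values use the minimum-likelihood convention with a 1+1e-9 relative
tolerance when accumulating tied masses; empirical permutation p-values
use the +1 correction; degenerate cases (constant inputs to
correlations, undefined z at zero null SD, regions truncated at
chromosome edges) raise or flag rather than silently producing numbers.

## Known limitations

The island caller's genome-bins BH correction is conservative and will
miss marginal islands a likelihood-ratio formulation might keep.  The
region-level DMR q (minimum member q) is conservative and not a
calibrated region FDR.  The exact conditional DE test equalises library
sizes by rounding scaled counts, which discards a small amount of
information relative to quantile-adjusted pseudo-likelihood approaches.
The valley "consistent" category with zero slack is sensitive to
single-site boundary noise between conditions; the slack parameter
exists for that reason but defaults to the strict definition.
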