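# Methods

## Overview

The package implements the computational arm of a chromatin-context
CRISPRa study as a testable pipeline: (i) genotyping and expression
quantification of a barcoded reporter pool, (ii) association of
reporter expression with chromatin state, histone-mark signal and TAD
architecture, (iii) an exponential-decay model of CRISPRa fold
activation versus basal expression with chromatin-state enrichment of
its residuals, (iv) single-cell CRISPRa processing (guide assignment,
QC, per-target activation tests), and (v) a two-latent-state
negative-binomial model of per-cell activation fitted by EM. A
synthetic-data generator produces every input with known ground truth.

## Synthetic-data generator

The generator's defaults are the study conditions; they were fixed
before the test suite was frozen and are not tuned per run.

**Genome.** `n_chromosomes=2` chromosomes of 1 Mb (plumbing scale, not
a biological claim) are tiled by chromatin-state segments with
exponential lengths (mean 2 kb). The ten states follow the usual
ChromHMM vocabulary (E2 active enhancer, E4/E5 flanking TSS, E6
bivalent, E7 quiescent, E8 polycomb, E9 ZNF/H3K9me3, E10 strong
transcription); state frequencies mirror the per-state reporter
proportions of the assay, with quiescent chromatin at ~72%. Six
histone-mark tracks carry each state's emission signature (e.g.
bivalent segments have both H3K4me3- and H3K27me3-like signal) with
multiplicative noise. TADs cover ~40% of the genome. Nucleotide
sequence is random with a smoothly varying AT field (mean 0.59, sd
0.05 after Gaussian smoothing); no real genome sequence is used.

**Reporter pool.** `n_insertions=2923` insertions (the size of the
confidently mapped pool in the assay) are drawn with probability
proportional to `exp(at_bias_strength * z_AT)` — the piggyBac AT
preference as a sampling weight on the local AT z-score. 48.7% of
reporters are silent (undetectable cDNA). Basal expression of the rest
is log-normal per state (active states around e^0.5–e^-0.5, repressed
around e^-3 to e^-4, sd 1 in log space). Differentiation dynamics add
a per-barcode linear trend in log expression (sd 1.2 across day 0 to
day 5), a shared per-TAD, per-timepoint shift (sd 0.5) that creates
within-TAD correlation, and timepoint noise (sd 0.3).

**Activation ground truth.** Log fold activation is
`A*exp(-k*log basal) + C + dev_state + noise` with defaults
`(A,k,C)=(0.15,0.45,0.05)` and noise sd 0.35, a bivalent boost of
+1 log unit and H3K9me3 damping of −0.5. The decay constants and
noise were chosen once so that the simulated assay reproduces the
study's regime — fit R² around 0.6 and roughly 55–60% of reporters
activated more than 2-fold — after accounting for counting noise in
the measured scores.

**Sequencing.** Inverse-PCR reads are
`anchor + barcode(17) + anchor + 30 nt genomic flank`; 5% of reads are
malformed (wrong barcode length or missing anchor); each enzyme
detects a barcode with probability 0.87, which makes ~75% of barcodes
dual-enzyme mapped. Amplicon tables draw gDNA ~ Poisson around 200
reads/barcode/replicate (with per-barcode copy-number and
per-replicate library-size log-normal factors, which give the
median-of-ratios normalization something real to undo) and cDNA ~
Poisson with mean gDNA x expression. The 200-read depth keeps the
<100-read coverage filter to genuinely shallow barcodes, as in the
deeply sequenced assay.

**Single-cell experiment.** Pools mix no-transfection : scramble :
on-target cells at 5:5:90. Total UMI is log-normal
(median 10,000, sd 0.3 in log). Every cell draws a count for every
target gene from the latent-state NB model; only the cell's own
perturbation can be active. Guides-per-cell follows a free
distribution over 0–8 whose marginals reproduce the observed ~6% zero
/ ~81% 1–5 / ~13% >5 split among transfected cells (the generative
process behind the observed multiplicity is not identified, so it is
exposed as a parameter). Mitochondrial fractions are Beta(4,60)
(mean ~6%, a tail past the 10% QC cutoff); 2% of cells are flagged
doublets. Background genes absorb the remaining UMIs so per-cell
counts sum exactly to the recorded total.

What the generator does **not** emulate: real sequence content, PCR
chimeras, ambient RNA, batch structure beyond scalar size factors,
gene–gene correlation, and doublet expression profiles (doublet flags
are consumed, not derived). Tests passing on synthetic data therefore
validate the algorithms' correctness and statistical behavior, not
robustness to those artifacts.

## Genotyping

Reads must match both anchors (≤1 mismatch each) with exactly 17 nt
between them and ≥20 nt of flank; rejects are tallied by reason.
Flanks are located by exact substring search against the synthetic
sequence (on real data a pre-aligned table replaces this step; the
bespoke logic is everything downstream of alignment). Candidate
locations of one barcode are merged by single linkage at 10 bp with
counts summed and the midpoint (rounded toward zero) as the location;
multiple surviving clusters mark the barcode ambiguous. Across the two
enzymes, agreement within 10 bp gives class "both" at the
read-count-weighted midpoint; one-enzyme barcodes are kept as
"single_enzyme"; disagreement or ambiguity in the only supporting
enzyme excludes the barcode.

## Expression and dynamics

Score = sum(cDNA)/sum(gDNA) per barcode and biological replicate;
barcodes under 100 total reads in a replicate are flagged low-coverage
and not scored. Samples are normalized with median-of-ratios size
factors (geometric-mean pseudo-reference over barcodes positive in
every sample). Dynamics groups use the day5/day0 fold change of
normalized scores: group 1 [0, 0.5), group 2 [0.5, 2] (both endpoints
closed — boundary assignment is otherwise ambiguous), group 3 > 2,
group 4 undetectable at either stage (gDNA present). The group
z-score is the standard (x − mean)/sd of the log fold change within a
group; the display pseudocount 1e-5 for non-expressed barcodes is
never used in classification. Safe-harbor candidates pass gDNA ≥ 20,
cDNA ≥ 20, mapping reads ≥ 30, unambiguous single site, and
intronic/intergenic annotation; the dynamics group is reported as a
column (constitutive candidates are group 2) rather than enforced.

## Chromatin context

Window sums integrate bedGraph signal over ±half_width (default 5 kb,
configurable 1–100 kb) with partial-interval arithmetic, clipped to
the chromosome. Expression bins are equal-size rank bins (ties broken
by stable input order); in the 8-bin scheme undetectable barcodes form
bin 1. Per-bin mean covariate is regressed on bin index by OLS. State
assignment takes the half-open segmentation interval containing the
insertion base. TAD analysis computes Pearson r of expression
trajectories for all co-TAD pairs (TADs with ≥2 barcodes, all
available timepoints) against an equal number of seeded random
cross-TAD pairs, compared by Welch's t; identical trajectories are
flagged degenerate instead of producing an undefined statistic.
Strand is ignored throughout (no strand-specific treatment is
defined for these analyses).

## Activation model

Fold activation compares the dCas9-VPR condition with the matched
scrambled-sgRNA control on shared normalization, keeping barcodes with
total gDNA ≥ 10 and detectable expression in both conditions. The
decay model `y = A exp(-k x) + C` (x = log basal, y = log fold, both
natural logs) is fitted by trust-region least squares with the
deterministic start `A = max(y) − min(y), k = 1, C = min(y)`, bound
k ≥ 0, tolerances 1e-12; flat data degenerates to `C = mean, R² = 0`.
Residuals are ranked into six equal bins (remainder to the lowest
bins; bin 6 = most hyper-activated). Per state x bin, observed counts
are tested against the state's overall proportion with a binomial test
and Benjamini–Hochberg correction; expected counts are state total /
n_bins so they sum exactly to the state total. Residual z-scores are
standardized globally (not per state) and compared across states by
one-way ANOVA.

## Single-cell processing

A guide is present at ≥1 UMI (no threshold is defined by the assay;
exposed as a parameter). Cells with 0 present guides are unassigned;
>5 excluded; 1–5 spanning more than one guide set excluded; otherwise
the cell takes the set's target. QC removes doublets and cells with
mitochondrial fraction >10% — the cutoff is read as 10 percent, since
a raw count of 10 would remove almost nothing at 10x depth — then
scales each cell to 10,000 counts. Per target, Welch's t compares
normalized target-gene expression in on-target vs scramble cells,
Bonferroni-corrected over all tested targets (a single global family);
targets under 40 cells are skipped. Zero fractions use raw counts; the
percentile rank places the on-target mean among per-gene means over
scramble cells.

## Latent-state NB model

Parameterization (fixed project-wide): NB variance = mu + mu²/theta.
E-step responsibilities use the current class parameters with control
cells clamped to r = 0 (controls define the basal state; the anchor is
a switch). M-step: per class, (beta0, beta_act, log theta) jointly
maximize the responsibility-weighted complete-data log-likelihood
(L-BFGS-B with analytic gradients, beta_act bounded ≥ 0 to pin the
"active" label to the higher-mean state, beta0 floored at −30 for
all-zero classes); pi is the mean responsibility over non-control
cells. Initialization is deterministic: r thresholded at the class
median of y/N among non-control cells, pi = 0.5, theta by method of
moments. Convergence at |Δ log-likelihood| < 1e-6, max 500
iterations; the trace is stored and must be non-decreasing. Per-class
dispersion is shared between the two latent states, and pi is
estimated per class (a per-target option exists through the class
labels). The gammaln/digamma terms are evaluated on the distinct
count values only, which dominates the runtime otherwise.

**Identifiability caution.** At weakly separated parameter points
(e.g. basal mean 0.014 and active mean 0.71 per 10⁴ UMIs with theta =
0.5, where an active cell still yields zero counts 64% of the time)
the likelihood has a flat ridge trading beta_act against pi and theta.
With few anchored control observations the global optimum can be
degenerate (pi → 1); a direct Nelder–Mead fit of the observed-data
likelihood confirms this is a property of the likelihood, not of the
EM. Recovery studies therefore anchor a control arm comparable to the
real design, where untransfected plus scramble cells supply basal
observations for every class in the tens of thousands; 2,000 controls
per class is a conservative stand-in. Per-fit estimates still scatter
along the ridge (sd ~0.4 on beta_act at 500 cells/class), so recovery
is assessed as bias over a multi-seed study rather than per fit.

## Problem sizes

Defaults used by the tests and the acceptance script: 2 x 1 Mb
genome, 2,923 reporters, 4 replicates, ~250k genotyping reads;
single-cell runs of 10–96 targets at 50–300 cells/target; EM recovery
at 10 classes x (500 + 2,000) cells over 20 seeds. These sizes keep
the full suite in a few minutes while leaving every statistical
property measurable at its stated tolerance.

## Known limitations

- Real-data alignment (HISAT2 etc.), peak calling, ChromHMM training,
  doublet calling and RNA-seq quantification are out of scope; their
  outputs are consumed as inputs.
- Welch's t on heavily zero-inflated normalized counts is conservative
  (observed null type-I well below nominal); the latent-state model is
  the principled treatment of those zeros.
- The decay model is fitted unweighted; measurement error in basal
  expression (the regressor) slightly attenuates k at shallow depth.
- The per-class NB fit assumes one dispersion for both latent states;
  state-specific dispersion is not identifiable at the study's
  per-class cell counts.
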