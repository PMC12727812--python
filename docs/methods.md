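# Methods

This note documents the models implemented in `tilescreen`, the choices made
where the design was genuinely open, what the synthetic-data generators do and
do not emulate, and the numerical conventions. All coordinates are 0-based
half-open throughout; 1-based positions appear only in spacer-internal
annotations (homopolymer starts) where bench convention is 1-based.

## Guide library design

Candidates are GN₁₉ guides: the genomic 20-mer adjacent to an NGG PAM with the
5′ base forced to G (U6 transcription start). Both strands of every target
interval are scanned; the protospacer must lie inside the target, the PAM may
extend past it.

**Perfect-match counting.** Because of the forced G, a guide's own genomic
site need not match its spacer at position 1. Perfect-match target sites are
therefore defined as genomic sites matching the 19-nt variable region
(positions 2–20) plus NGG — the guide's own site always counts, and the same
convention is used when counting spacers in raw screen reads. Candidates with
more than one perfect-match site are removed.

**Off-target surrogates.** Mismatch-model off-target scorers are pluggable.
The default specificity surrogate is `1/(1 + Σ_sites 0.5^mm)` over sites with
≤ 3 variable-region mismatches (own site excluded), and predicted off-target
activity is `max_sites 0.5^mm`. Both are monotone in off-target burden, lie in
[0, 1], and use the same thresholds as published mismatch models (reject
specificity < 0.2 or activity > 0.8); they are deliberately simple so that the
*selection logic* downstream, not a particular neural scorer, is what the
package tests. The on-target scorer defaults to a deterministic hash of the
spacer in [0, 1): reproducible, distribution-free, replaceable via
`ON_TARGET_SCORERS`.

**Selection.** Bins are fixed 50-bp frames from chromosome coordinate 0 keyed
on the protospacer start. Stage 1 keeps the best-scoring candidate per bin per
target; stage 2, for targets under 10 guides, admits the 2nd, 3rd, … best of
every bin in lockstep; stage 3 tops deficient targets up from ±250 bp flank
candidates until 5 guides. Ties break by (score desc, coordinate asc, spacer
lexicographic), making selection a pure function of (candidates, scores,
policy) — permutation-invariance is asserted in tests.

## Screen statistics

**Normalization.** Median-of-ratios size factors, computed on a control-guide
subset when one is given (control normalization is what makes a screen where
*most* guides drop out interpretable), rescaled to geometric mean 1.

**Dispersion.** Per-guide method-of-moments `alpha = (v - m)/m²` pooled within
experimental conditions, a least-squares trend `alpha(mu) = a0 + a1/mu`, and a
log-scale normal–normal shrinkage: the sampling variance of a log variance
estimate at d residual df is `trigamma(d/2)` and its bias is
`psi(d/2) − log(d/2)`; the between-guide prior variance is estimated from the
MAD of log-MoM residuals around the trend after subtracting the sampling
variance. With the 2–6 residual df of a typical screen the trend dominates and
null Wald z-scores come out with unit variance (asserted by a KS test in the
suite); genuinely heterogeneous dispersions would retain per-guide weight. An
early fixed-weight blend (half log-MoM, half trend) was measured to inflate
null z sd to 1.1–1.5 and was replaced by this estimator.

**Exclusion rules.** Guides are excluded post hoc when the spacer contains a
GGGG starting at 1-based position ≥ 6 or a CCCC starting at positions 10–12
(central G₄/C₄ homopolymers show pervasive off-target proliferation effects;
the diagnostic `homopolymer_enrichment` reproduces that analysis on all
guides), or when enriched (log₂FC ≥ 1) from initial abundance at or below the
5th percentile. The homopolymer rule is evaluated on *any* matching substring,
so a longer run starting earlier still triggers it.

**Windows.** Per-hDel windows start at the hDel start, step by the scheme's
step, and the last window clips at the hDel end; a guide joins every window
containing its protospacer midpoint; windows with < 5 guides are dropped.
Windows are per-hDel objects (not chromosome-frame bins) and may extend into
flanks via `flank_extent` when flank guides exist.

**α-RRA.** Percentiles come from ranking all included guides by one-tailed p;
α is the percentile of the worst guide at tail BH FDR < 0.05 (α = 0 flags the
run as degenerate and all ρ = 1). ρ is the minimum Beta order-statistic
probability over selected percentiles. The null draws window-sized percentile
sets with replacement from the empirical grid {1/N, …, 1}; pools with N^n ≤
4096 are enumerated exhaustively so tiny cases are exact. The empirical p
carries a +1 pseudo-count and so never returns 0. Both tails are computed; the
reported window statistic is the tail with the smaller BH q, labeled with its
direction, and the effect is the alphamean (mean log₂FC of the selected
guides).

**Stouffer windows.** Guide Wald z are robustly standardized (median/MAD over
all included guides) and combined as `Z = Σ z_i / √n`. The default p-value
compares |Z| to window-sized resamples of the observed z pool with the same
+1 pseudo-count as the rank-aggregation null; this keeps the false-window rate
at its nominal level even when small-sample Wald z deviate slightly from
N(0,1). A standard-normal reference (`null="normal"`) implements the textbook
formula and backs the closed-form unit tests.

## Single-cell assignment

QC removes a cell failing *any* criterion: genes detected or total UMIs
strictly below the matrix's own 10th-percentile floors, mitochondrial fraction
above 15%, or (high-MOI mode) below 1%. The percentile thresholds are
realized, not fixed; re-filtering with the same realized thresholds removes
nothing.

Each sgRNA's counts across cells are modeled as
`(1 − π)·Poisson(λ) + π·G(μ, σ)` where `G` is a Gaussian on log₂ counts
discretized onto c ≥ 1: bin edges at `log2(c ± 0.5)` (lower edge of c = 1 at
log₂ 0.5), renormalized by `1 − Φ((−1 − μ)/σ)`, with zero counts carrying no
signal mass. The same law drives the simulator, so generator and fitter are
conjugate and parameter recovery is a fair test. EM updates π and λ in closed
form; (μ, σ) first try the responsibility-weighted log₂ moments and fall back
to Nelder-Mead maximization of the expected complete log-likelihood, accepting
only non-decreasing values — the observed log-likelihood is therefore provably
monotone (asserted per-iteration in tests). Initialization: λ from counts at
or below the median, (μ, σ, π) from counts above the 90th percentile;
convergence at relative change < 1e-6 within 250 iterations, with up to 3
seeded jittered restarts; σ floored at 0.05. An all-zero vector yields a
degenerate fit (π = 0) rather than an error.

Cells are assigned a guide at posterior > 0.5 (strict). Low-MOI mode keeps
only cells with exactly one assignment for downstream analysis — the
conservative reading when one integration per cell is expected; high-MOI mode
keeps all cells with at least one.

## Pseudobulk differential expression and cis calibration

Genes detected in fewer than 10% of cells are dropped *before* pseudobulking.
UMIs are summed exactly per (group, GEM well); the reference is either cells
carrying non-targeting guides (low-MOI design) or all other cells excluding
carriers of any guide targeting the same hDel (high-MOI design). Each gene is
tested by an LRT between NB GLMs `~well + group` and `~well` (χ²₁ on the
deviance difference), sharing a dispersion estimated from Poisson full-model
residuals and shrunk toward a 1/μ trend. The GEM well enters as well-specific
intercepts only, matching the reduced model.

Cis calling: `t = log2FC/se` per pair; each gene's null is the t of its pairs
with sgRNAs targeting ≥ 100 kb from its TSS (distance = |protospacer midpoint
− TSS|, infinite across chromosomes). The gene-specific standardization *is*
the z-score normalization; genes with fewer than 50 null pairs or zero null sd
are flagged and receive no p. BH runs only over pairs within ≤ 100 kb; distal
pairs never receive a q. The null condition is read gene-centrically (the
pair's own sgRNA ≥ 100 kb from that gene) so every gene's null is estimable
from many guides.

Trans profiling pools all of an hDel's guides into one target group, tests
genome-wide, BH-adjusts across genes, and reports the inter-guide log₂FC
correlation over hit genes as a specificity diagnostic.

## Interval enrichment

The blacklist marks bases covered by any 50-mer (canonicalized over strands)
occurring more than once genome-wide, merged into runs ≥ 1 kb, unioned with
NUMT intervals. Null sets relocate 500-kb blocks of the (merged) focal
intervals uniformly over positions where the whole block fits inside one
blacklist-free segment — across chromosomes by default — preserving
within-block offsets; features that land outside a chromosome or touch the
blacklist are dropped. This is a deliberate simplification of
segmentation-aware block bootstrapping: placement is uniform over eligible
sequence rather than proposal-weighted, which the analytic-expectation test
(mean null intersection = bp_A·bp_B/genome bp) validates. Empirical p-values
use strict inequalities, so a tie counts for neither tail, and zero counts are
reported as "< 1/n_sets". A peak intersects an hDel only when at least half
the peak's length overlaps it (inclusive at exactly half).

## Synthetic data: what it emulates and what it does not

Screen counts are NB with log-normal per-guide abundance (sd 0.3), log-normal
size factors (sd 0.1), and a planted per-window log₂ fold-change acting
multiplicatively by timepoint. Perturb-seq gene counts are NB with log-normal
gene means, per-GEM-well log-normal multiplicative offsets (sd 0.1, absorbable
by a well covariate), mitochondrial genes scaled to a 5% expected UMI share,
and planted cis/trans effects scaling means only in truly infected cells.
Infections are independent Bernoulli per (cell, guide) with Σπ set to the MOI
target: 1 for the low-MOI regime (fraction of cells with ≥ 2 infections ≈
0.26, bounded at 0.30 in tests) and 7 for the high-MOI regime (realized median
7). Capture counts mix ambient Poisson (rate ~0.2) with the discretized
log₂-Gaussian (mean ~9, sd 1), i.e. signal/background separation ≈ 9 — well
above the ≥ 4 regime where assignment precision/recall ≥ 0.95 is asserted.

Not emulated: doublets, ambient mRNA contamination in the gene matrix, barcode
errors, read-level sequencing noise for the single-cell assay,
guide-efficiency heterogeneity, and chromatin-context effects on CRISPRi
efficacy. Passing tests therefore demonstrate the *statistical machinery* —
normalization, testing, aggregation, calibration, assignment — under the
stated noise model, not robustness to every artifact of real droplet data.

## Study conditions used by the validation experiments

- Planted-window recovery: 2,020 hDels × 10 guides (20 planted at −1.5 log₂),
  two individuals × two technical replicates (paired design `~individual +
  time`), depth 1000× (screens maintain ≥ 1000× library representation),
  NB dispersion 0.05; both aggregators at q < 0.1 with 10,000 permutations.
- Stouffer null calibration: 2,000 windows × 5 guides, three technical
  replicates, depth 500×, dispersion 0.05.
- NB recovery: 2,000 guides planted at +1 log₂ against 2,000 non-targeting
  controls (control normalization), depth 1000×, dispersion 0.1.
- Mixture recovery: 5,000 cells, λ = 0.3, μ = 8, σ = 1, π = 0.2.
- Cis type-I error: 110 guides, 4,000 cells, high-MOI design with the
  all-other-cells reference, ~25 genes after detection filtering.
- Enrichment expectation: two 100-kb chromosomes, 2-kb blocks, 1,000 null
  sets.

These sizes keep the full suite within a few minutes on one CPU while leaving
every Monte-Carlo tolerance (3 × MC-sd bands, KS p > 0.01) meaningful.

## Known limitations

- The NB engine is a single-dispersion-per-feature Wald/LRT GLM; it does not
  reimplement MAP dispersion estimation or LFC shrinkage from reference
  bulk-RNA tools, and guide-level p-values at 4 samples are approximate —
  which is exactly why both window aggregators use empirical nulls.
- Off-target surrogates rank guides sensibly but are not trained activity
  models; swap in a real scorer for production library design.
- Block relocation ignores GC/length matching; enrichment conclusions are
  relative to a uniform-placement null over mappable sequence.
- `peak_hdel_intersections` and `overlap_lengths` are quadratic per
  chromosome — fine at the fixture scales here, not for million-interval
  inputs.
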