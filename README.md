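# tilescreen

Analysis toolkit for genome-scale **tiling CRISPRi screens** of deletion
intervals — in particular human-specific deletions (hDels): sequences present
in the chimpanzee genome but lost in the human lineage. A tiling screen places
dense sgRNAs across every interval of interest, measures their enrichment or
depletion during cell proliferation, and localizes functional sub-sequences by
aggregating guide-level statistics over genomic windows. Follow-up
direct-capture Perturb-seq maps each functional element to its *cis* target
genes at single-cell resolution.

`tilescreen` implements the complete computational path, exercised end to end
on synthetic data with planted ground truth:

- **`guide_library`** — GN₁₉ candidate enumeration against NGG PAMs on both
  strands, exact-match and mismatch off-target filtering (>1 perfect-match
  site, specificity < 0.2, predicted off-target activity > 0.8, TTTT motifs),
  50-bp binning and a three-stage tiling selection policy (best per bin →
  deeper ranks per bin until ≥ 10 guides per target → ±250 bp flank rescue to
  ≥ 5), homopolymer annotation and manifest assembly.
- **`screen_stats`** — median-of-ratios size factors, per-sgRNA
  negative-binomial GLM Wald tests with trend-shrunk dispersions,
  homopolymer/abundance exclusion rules, per-hDel genomic windows
  (overlapping 500 bp / 250-bp step, or non-overlapping 250 bp), and two
  window aggregators: **α-robust rank aggregation** with a permutation null
  and **Stouffer's method** on standardized guide z-scores.
- **`sc_assign`** — single-cell QC and sgRNA-to-cell assignment by a
  per-sgRNA two-component mixture (ambient Poisson vs a discretized Gaussian
  on log₂ UMIs) fit by EM; assignment at posterior > 0.5, in low-MOI
  (~1 sgRNA/cell) and high-MOI (~7 sgRNAs/cell) modes.
- **`perturb_de`** — exact pseudobulk sums per (sgRNA, GEM well),
  negative-binomial likelihood-ratio tests of `~well + sgRNA` vs `~well`,
  gene-specific empirical-null calibration of per-pair t-statistics, BH
  adjustment restricted to sgRNA–gene pairs within 100 kb, and genome-wide
  *trans* profiling per hDel.
- **`feature_enrichment`** — 50-mer mappability blacklists, 500-kb
  block-resampled null interval sets, strict-count empirical
  enrichment/depletion p-values, and the "at least half of a peak" overlap
  rule.
- **`synthetic_data`** — generators for genome fixtures, screen counts and
  Perturb-seq matrices whose planted effects make every stage testable.

## The statistics at the core

**Per-sgRNA test.** Counts `K_sj ~ NB(mu_sj, alpha_s)` with
`log mu_sj = log s_j + beta_0 + beta_ind + beta_t x_t(j)`, size factors `s_j`
by median-of-ratios (optionally on control guides only), and dispersion
`alpha_s` estimated by within-condition method of moments shrunk on the log
scale toward a fitted `alpha(mu) = a0 + a1/mu` trend with an
empirically-estimated prior weight. The Wald z on the time coefficient gives
two-sided and one-tailed (depletion/enrichment) p-values.

**α-RRA.** Guides are ranked by tail p into percentiles `u = rank/N`; the
selection threshold α is the percentile of the worst guide at BH FDR < 0.05.
For a window with sorted selected percentiles `u_(1) … u_(k)`,

    rho = min_{i<=k} P(Beta(i, n-i+1) <= u_(i)),

compared against window-sized draws from the empirical percentile grid
(exhaustively enumerated for tiny pools); BH within each tail.

**Stouffer windows.** `Z_w = sum_i z_i / sqrt(n)` over robustly standardized
guide z-scores, with a guide-resampling empirical null (a standard-normal
reference is available as an option).

**Cis calibration.** For each gene, `t = log2FC/se` of pairs whose sgRNA
targets ≥ 100 kb away form the empirical null; `z = (t - mean_null)/sd_null`,
`p = 2 Phi(-|z|)`, BH over pairs within ≤ 100 kb only.

**Interval enrichment.** Observed intersection bp against 1000 null sets
built by relocating 500-kb blocks of the focal intervals uniformly over the
blacklist-free genome; `p_enrich` counts null sets with strictly greater
intersection (`p < 1/n_sets` reported when none).

## Worked example

Design a tiling library on a synthetic fixture, plant a −2 log₂
proliferation effect in the first 250 bp of one hDel, and localize it:

```python
from tilescreen import synthetic_data as syn, guide_library as gl, screen_stats as ss
from tilescreen.intervals import GenomicInterval

fixture = syn.generate_genome_fixture(seed=1)
candidates = gl.score_offtargets_table(
    gl.enumerate_candidates(fixture, fixture.hdels), fixture)
kept, rejected = gl.filter_candidates(candidates)
selection = gl.select_tiling_library(kept, gl.SelectionPolicy())
print(f"{len(candidates)} candidates -> {len(kept)} pass filters -> "
      f"{len(selection.selected)} selected ({len(selection.deficient)} deficient hDels)")

manifest = gl.assemble_manifest({"hdel": selection.selected})
h = fixture.hdels.iloc[0]
window = GenomicInterval(h.chrom, int(h.start), int(h.start) + 250)
truth = syn.make_screen_truth(manifest, planted=[(window, -2.0)], depth=1000,
                              dispersion=0.05, n_replicates=3, seed=2)
counts = syn.simulate_screen(manifest, truth, seed=3)

stats = ss.fit_nb_glm(counts, design=("time",))
wmap = ss.assign_windows(manifest, fixture.hdels, ss.WindowScheme(500, 250, 5))
res = ss.alpha_rra(wmap, stats, ss.RraConfig(seed=4))
top = res.sort_values("q").iloc[0]
print(f"top window {top.name}: rho={top['rho']:.2e} q={top['q']:.4f} "
      f"effect={top['effect']:+.2f} log2 ({top['direction']})")
```

prints

```
1888 candidates -> 1764 pass filters -> 354 selected (0 deficient hDels)
top window hDel_0000:4814-5314: rho=1.34e-07 q=0.0058 effect=-2.16 log2 (depleted)
```

The only window called at q < 0.1 (of 58 tested) is the one containing the
planted effect, with the alphamean effect estimate −2.16 log₂ close to the
planted −2.

A `tilescreen` command-line interface chains the same stages on files:
`tilescreen simulate | design | count | screen-test | windows | assign |
pseudobulk | cis | trans | enrich` (see `tilescreen --help`).

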