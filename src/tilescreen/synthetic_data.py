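"""Synthetic data with planted ground truth for every pipeline stage.

Three generators:

* :func:`generate_genome_fixture` — toy genome (random sequence), a set of
  disjoint deletion intervals (hDels, the tiling targets), a TSS annotation
  with mitochondrial flags, per-assay peak sets and a blacklist.
* :func:`simulate_screen` — negative-binomial sgRNA counts at t0/tfinal with
  per-sample size factors and planted per-window proliferation effects.
* :func:`simulate_perturbseq` — sparse single-cell UMI matrices: gene counts
  are NB with per-GEM-well multiplicative offsets and planted cis/trans
  effects; sgRNA capture counts mix an ambient Poisson background with a
  discretized log2-Gaussian signal in truly infected cells, under a low-MOI
  (median ~1 sgRNA/cell) or high-MOI (median ~7) regime.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .distributions import sample_log2_gaussian, sample_negative_binomial
from .intervals import GenomicInterval, as_interval_frame

DEFAULT_ASSAYS = ("atac", "h3k4me1", "h3k27ac")


# ---------------------------------------------------------------------------
# genome fixture
# ---------------------------------------------------------------------------

@dataclass
class GenomeFixture:
    """Toy genome: sequences plus the annotation tracks the pipeline consumes."""

    sequences: dict  # chrom -> DNA string
    hdels: pd.DataFrame  # chrom, start, end, name
    genes: pd.DataFrame  # gene_id, chrom, tss, strand, mito
    peaks: dict = field(default_factory=dict)  # assay -> interval frame
    blacklist: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end"])
    )

    def chrom_sizes(self) -> dict:
        return {c: len(s) for c, s in self.sequences.items()}


def generate_genome_fixture(
    chrom_sizes: dict | None = None,
    n_hdels: int = 20,
    hdel_min_len: int = 50,
    hdel_median_len: int = 626,
    hdel_max_len: int = 2000,
    gene_spacing: int = 20_000,
    n_mito_genes: int = 3,
    peaks_per_assay: int = 15,
    peak_len: int = 300,
    seed: int = 0,
) -> GenomeFixture:
    """Generate a deterministic toy genome fixture.

    hDels are placed disjointly inside the first 40% of each chromosome so
    that every hDel has genes both within 100 kb (the tiled gene grid) and
    beyond 100 kb (genes parked at the chromosome end). hDel lengths are
    log-normal with the requested median, clipped to [min, max]; real
    human-specific deletions have a median length of a few hundred bp and
    nothing shorter than the structural-variant floor (50 bp) is emitted.
    """
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 200_000, "chr2": 200_000}
    if any(sz <= 0 for sz in chrom_sizes.values()):
        raise ValueError("chromosome sizes must be positive")
    rng = np.random.default_rng(seed)

    genome_bp = sum(chrom_sizes.values())
    if n_hdels * hdel_min_len > genome_bp:
        raise ValueError(
            f"infeasible config: {n_hdels} hDels of >= {hdel_min_len} bp "
            f"exceed the {genome_bp} bp genome"
        )

    sequences = {
        chrom: "".join(rng.choice(list("ACGT"), size=size))
        for chrom, size in chrom_sizes.items()
    }

    # partition hDels across chromosomes proportionally to size
    chroms = list(chrom_sizes)
    per_chrom = np.zeros(len(chroms), dtype=int)
    for i in rng.choice(len(chroms), size=n_hdels, p=np.array(
            [chrom_sizes[c] for c in chroms], dtype=float) / genome_bp):
        per_chrom[i] += 1

    sigma = 0.6  # log-normal shape for hDel lengths
    hdel_rows = []
    k = 0
    for chrom, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        # cap the placement zone so a gene parked at the chromosome end is
        # always > 100 kb from every hDel midpoint
        zone = min(int(0.4 * chrom_sizes[chrom]), chrom_sizes[chrom] - 101_000)
        if zone <= 0:
            raise ValueError(
                f"{chrom} is too short to host hDels with genes beyond 100 kb"
            )
        slot = zone // n_c
        if slot <= hdel_min_len + 1:
            raise ValueError(
                f"infeasible config: cannot fit {n_c} disjoint hDels in the "
                f"{zone} bp placement zone of {chrom}"
            )
        for j in range(n_c):
            length = int(np.clip(
                np.round(hdel_median_len * np.exp(sigma * rng.standard_normal())),
                hdel_min_len, min(hdel_max_len, slot - 1),
            ))
            start = j * slot + int(rng.integers(0, slot - length))
            hdel_rows.append((chrom, start, start + length, f"hDel_{k:04d}"))
            k += 1
    hdels = pd.DataFrame(hdel_rows, columns=["chrom", "start", "end", "name"])

    # genes: a grid across the hDel zone (+100 kb) plus far genes at the end
    gene_rows = []
    g = 0
    for chrom, size in chrom_sizes.items():
        zone = min(int(0.4 * size), size - 101_000)
        for pos in range(gene_spacing // 2, min(zone + 100_000, size), gene_spacing):
            tss = int(pos + rng.integers(-gene_spacing // 4, gene_spacing // 4))
            tss = int(np.clip(tss, 0, size - 1))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_rows.append((f"gene_{g:04d}", chrom, tss, strand, False))
            g += 1
        # distal genes guaranteed > 100 kb from any hDel midpoint in the zone
        for pos in (size - 2, size - 1000):
            if pos - zone > 100_000:
                gene_rows.append((f"gene_{g:04d}", chrom, int(pos), "+", False))
                g += 1
    last = chroms[-1]
    for m in range(n_mito_genes):
        gene_rows.append(
            (f"mito_{m}", last, int(chrom_sizes[last] - 3000 - 10 * m), "+", True)
        )
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "tss", "strand", "mito"])

    peaks = {}
    for assay in DEFAULT_ASSAYS:
        rows = []
        for _ in range(peaks_per_assay):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, chrom_sizes[chrom] - peak_len))
            rows.append((chrom, start, start + peak_len))
        peaks[assay] = as_interval_frame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)

    fixture = GenomeFixture(sequences=sequences, hdels=hdels, genes=genes, peaks=peaks)
    _check_fixture(fixture)
    return fixture


def _check_fixture(fx: GenomeFixture) -> None:
    sizes = fx.chrom_sizes()
    for _, row in fx.hdels.iterrows():
        if not (0 <= row.start < row.end <= sizes[row.chrom]):
            raise AssertionError("hDel outside chromosome bounds")
        mid = (row.start + row.end) // 2
        sub = fx.genes[fx.genes["chrom"] == row.chrom]
        d = (sub["tss"] - mid).abs()
        if not ((d <= 100_000).any() and (d > 100_000).any()):
            raise AssertionError(
                f"{row['name']}: fixture must have genes within and beyond 100 kb"
            )
    if fx.hdels["name"].duplicated().any():
        raise AssertionError("hDel ids not unique")


# ---------------------------------------------------------------------------
# screen counts
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    """Planted ground truth for one simulated proliferation screen."""

    lfc: pd.Series  # per-sgRNA true log2 fold-change over the screen
    base_abundance: pd.Series  # per-sgRNA relative abundance q_s (mean 1)
    dispersion: pd.Series  # per-sgRNA NB dispersion alpha_s
    size_factors: pd.Series  # per-sample s_j
    samples: pd.DataFrame  # sample, timepoint, replicate, individual
    planted_windows: pd.DataFrame  # chrom, start, end, lfc

    def __post_init__(self) -> None:
        if (self.dispersion < 0).any():
            raise ValueError("dispersions must be >= 0")
        if (self.size_factors <= 0).any():
            raise ValueError("size factors must be > 0")


def make_screen_truth(
    manifest: pd.DataFrame,
    planted: list | None = None,
    n_replicates: int = 2,
    n_individuals: int = 1,
    depth: float = 500.0,
    dispersion: float = 0.1,
    abundance_sd: float = 0.3,
    size_factor_sd: float = 0.1,
    seed: int = 0,
) -> ScreenTruth:
    """Build a ScreenTruth for a manifest.

    ``planted`` is a list of (GenomicInterval, lfc): hDel-targeting sgRNAs
    whose protospacer midpoint falls in the interval receive that true log2
    fold-change. Non-targeting sgRNAs always have lfc 0.
    """
    rng = np.random.default_rng(seed)
    ids = manifest["id"].to_numpy()
    lfc = pd.Series(0.0, index=ids)
    if planted:
        mid = ((manifest["start"].fillna(-1) + manifest["end"].fillna(-1)) // 2).to_numpy()
        chrom = manifest["chrom"].to_numpy()
        for iv, effect in planted:
            iv = iv if isinstance(iv, GenomicInterval) else GenomicInterval(*iv)
            hit = (chrom == iv.chrom) & (mid >= iv.start) & (mid < iv.end)
            lfc[hit] = effect
    if "category" in manifest:
        lfc[(manifest["category"] == "non-targeting").to_numpy()] = 0.0

    base = pd.Series(np.exp(abundance_sd * rng.standard_normal(len(ids))), index=ids)
    base *= depth / base.mean()
    disp = pd.Series(float(dispersion), index=ids)

    rows = []
    for ind in range(n_individuals):
        for rep in range(n_replicates):
            for tp in ("t0", "tfinal"):
                rows.append((f"ind{ind}_rep{rep}_{tp}", tp, f"rep{rep}", f"ind{ind}"))
    samples = pd.DataFrame(rows, columns=["sample", "timepoint", "replicate", "individual"])
    sf = np.exp(size_factor_sd * rng.standard_normal(len(samples)))
    sf /= np.exp(np.mean(np.log(sf)))
    size_factors = pd.Series(sf, index=samples["sample"].to_numpy())

    planted_rows = [
        (iv.chrom if isinstance(iv, GenomicInterval) else iv[0],
         iv.start if isinstance(iv, GenomicInterval) else iv[1],
         iv.end if isinstance(iv, GenomicInterval) else iv[2],
         effect)
        for iv, effect in (planted or [])
    ]
    planted_windows = pd.DataFrame(planted_rows, columns=["chrom", "start", "end", "lfc"])
    return ScreenTruth(lfc, base, disp, size_factors, samples, planted_windows)


def simulate_screen(manifest: pd.DataFrame, truth: ScreenTruth, seed: int = 0):
    """Simulate an sgRNA x sample count table.

    counts_sj ~ NB(mean = s_j * q_s * 2**(lfc_s * t_j), dispersion alpha_s)
    with t_j = 0 at t0 and 1 at tfinal.
    """
    from .screen_stats import ScreenCounts

    missing = set(manifest["id"]) - set(truth.lfc.index)
    if missing:
        raise KeyError(f"manifest sgRNAs missing from truth: {sorted(missing)[:3]} ...")
    rng = np.random.default_rng(seed)
    ids = manifest["id"].to_numpy()
    q = truth.base_abundance.loc[ids].to_numpy()
    lfc = truth.lfc.loc[ids].to_numpy()
    alpha = truth.dispersion.loc[ids].to_numpy()
    t = (truth.samples["timepoint"] == "tfinal").to_numpy().astype(float)
    s = truth.size_factors.loc[truth.samples["sample"]].to_numpy()
    mean = s[None, :] * q[:, None] * np.exp2(lfc[:, None] * t[None, :])
    counts = sample_negative_binomial(rng, mean, alpha[:, None])
    mat = pd.DataFrame(counts, index=ids, columns=truth.samples["sample"].to_numpy())
    return ScreenCounts(counts=mat, samples=truth.samples.copy())


# ---------------------------------------------------------------------------
# Perturb-seq
# ---------------------------------------------------------------------------

@dataclass
class PerturbTruth:
    """Planted ground truth for one simulated direct-capture Perturb-seq run."""

    sgrnas: pd.DataFrame  # id-indexed: ambient_rate, signal_mean, signal_sd,
    #                       signal_fraction, hdel_id, chrom, target_mid
    genes: pd.DataFrame  # gene_id-indexed: base_mean, dispersion, chrom, tss, mito
    n_gem_wells: int
    well_offsets: pd.DataFrame  # gene x well multiplicative offsets
    cis_effects: pd.DataFrame  # sgrna, gene, lfc
    trans_effects: pd.DataFrame  # sgrna, gene, lfc
    moi_mode: str = "low"

    def __post_init__(self) -> None:
        s = self.sgrnas
        if ((s["signal_fraction"] < 0) | (s["signal_fraction"] > 1)).any():
            raise ValueError("signal fractions must be in [0, 1]")
        if (s["signal_sd"] <= 0).any():
            raise ValueError("signal sds must be > 0")
        if (s["ambient_rate"] <= 0).any():
            raise ValueError("ambient rates must be > 0")


def make_perturb_truth(
    manifest: pd.DataFrame,
    fixture: GenomeFixture,
    moi_mode: str = "low",
    target_moi: float | None = None,
    n_gem_wells: int = 5,
    ambient_rate: float = 0.2,
    signal_mean: float = 9.0,
    signal_sd: float = 1.0,
    gene_mean_log_sd: float = 1.0,
    gene_base_mean: float = 5.0,
    gene_dispersion: float = 0.1,
    well_offset_sd: float = 0.1,
    mito_fraction: float = 0.05,
    cis_effects: list | None = None,
    trans_effects: list | None = None,
    seed: int = 0,
) -> PerturbTruth:
    """Default study conditions for the single-cell simulator.

    MOI regimes set a common per-cell infection probability so that the
    number of true infections per cell is Binomial(S, moi/S): median ~1 in
    the low-MOI regime (``target_moi`` 1.0) and ~7 in the high-MOI regime
    (7.0), matching the two screen configurations. Signal capture defaults
    (log2 mean 9, sd 1 against ambient Poisson rate 0.2) give the strong
    signal/background separation seen in real direct-capture data.
    """
    rng = np.random.default_rng(seed)
    if target_moi is None:
        target_moi = {"low": 1.0, "high": 7.0}[moi_mode]
    ids = manifest["id"].to_numpy()
    n_s = len(ids)
    sg = pd.DataFrame(index=pd.Index(ids, name="id"))
    sg["ambient_rate"] = ambient_rate * np.exp(0.3 * rng.standard_normal(n_s))
    sg["signal_mean"] = signal_mean + 0.5 * rng.standard_normal(n_s)
    sg["signal_sd"] = np.full(n_s, signal_sd)
    sg["signal_fraction"] = min(target_moi / n_s, 1.0)
    sg["hdel_id"] = manifest.get("hdel_id", pd.Series([""] * n_s, index=manifest.index)).to_numpy()
    sg["chrom"] = manifest["chrom"].to_numpy()
    start = pd.to_numeric(manifest["start"], errors="coerce").fillna(-1).to_numpy()
    end = pd.to_numeric(manifest["end"], errors="coerce").fillna(-1).to_numpy()
    sg["target_mid"] = ((start + end) // 2).astype(int)

    genes = fixture.genes.set_index("gene_id").copy()
    base = gene_base_mean * np.exp(gene_mean_log_sd * rng.standard_normal(len(genes)))
    mito = genes["mito"].to_numpy()
    if mito.any() and mito_fraction > 0:
        # scale mitochondrial means to the target expected UMI share
        target = mito_fraction / (1 - mito_fraction) * base[~mito].sum()
        base[mito] *= target / base[mito].sum()
    genes["base_mean"] = base
    genes["dispersion"] = gene_dispersion

    well_offsets = pd.DataFrame(
        np.exp(well_offset_sd * rng.standard_normal((len(genes), n_gem_wells))),
        index=genes.index,
        columns=[f"well{w}" for w in range(n_gem_wells)],
    )

    cis = pd.DataFrame(cis_effects or [], columns=["sgrna", "gene", "lfc"])
    trans = pd.DataFrame(trans_effects or [], columns=["sgrna", "gene", "lfc"])
    return PerturbTruth(sg, genes, n_gem_wells, well_offsets, cis, trans, moi_mode)


@dataclass
class PerturbSeqData:
    """Simulated single-cell dataset: gene and sgRNA AnnData plus ground truth."""

    genes: ad.AnnData  # cells x genes UMI matrix; obs carries gem_well
    sgrnas: ad.AnnData  # cells x sgRNAs capture matrix
    infections: np.ndarray  # boolean cells x sgRNAs ground truth


def simulate_perturbseq(
    truth: PerturbTruth,
    n_cells: int = 2000,
    library_size_sd: float = 0.25,
    seed: int = 0,
) -> PerturbSeqData:
    """Simulate gene-expression and sgRNA-capture UMI matrices.

    Each (cell, sgRNA) is truly infected with probability pi_s. Infected
    cells draw capture counts from the discretized log2-Gaussian
    (mu_s, sigma_s); all others draw ambient Poisson(lambda_s). Gene counts
    are NB with per-GEM-well multiplicative offsets; planted cis/trans
    effects scale the target gene's mean in truly infected cells only.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    sg = truth.sgrnas
    n_s = len(sg)
    gene_ids = truth.genes.index.to_numpy()
    n_g = len(gene_ids)

    wells = np.array([f"well{w}" for w in rng.integers(0, truth.n_gem_wells, n_cells)])
    barcodes = np.array([f"cell{i:05d}" for i in range(n_cells)])

    pi = sg["signal_fraction"].to_numpy()
    infected = rng.random((n_cells, n_s)) < pi[None, :]

    # sgRNA capture matrix
    lam = sg["ambient_rate"].to_numpy()
    cap = rng.poisson(np.broadcast_to(lam[None, :], (n_cells, n_s))).astype(np.int64)
    for j in range(n_s):
        idx = np.flatnonzero(infected[:, j])
        if idx.size:
            cap[idx, j] = sample_log2_gaussian(
                rng, float(sg["signal_mean"].iloc[j]), float(sg["signal_sd"].iloc[j]), idx.size
            )

    # gene expression matrix
    lib = np.exp(library_size_sd * rng.standard_normal(n_cells))
    base = truth.genes["base_mean"].to_numpy()
    well_mult = truth.well_offsets.to_numpy()  # genes x wells
    well_idx = np.array([int(w[4:]) for w in wells])
    mean = lib[:, None] * base[None, :] * well_mult[:, well_idx].T
    log2_effect = np.zeros((n_cells, n_g))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    sg_pos = {s: i for i, s in enumerate(sg.index)}
    for eff in (truth.cis_effects, truth.trans_effects):
        for _, row in eff.iterrows():
            j, gi = sg_pos[row["sgrna"]], gene_pos[row["gene"]]
            log2_effect[infected[:, j], gi] += row["lfc"]
    mean *= np.exp2(log2_effect)
    gx = sample_negative_binomial(rng, mean, truth.genes["dispersion"].to_numpy()[None, :])

    obs = pd.DataFrame({"gem_well": wells}, index=pd.Index(barcodes, name="barcode"))
    gvar = truth.genes.reset_index().set_index("gene_id")[["chrom", "tss", "strand", "mito"]]
    genes_ad = ad.AnnData(X=sparse.csr_matrix(gx), obs=obs.copy(), var=gvar)
    svar = sg[["hdel_id", "chrom", "target_mid"]].copy()
    sgrna_ad = ad.AnnData(X=sparse.csr_matrix(cap), obs=obs.copy(), var=svar)
    return PerturbSeqData(genes=genes_ad, sgrnas=sgrna_ad, infections=infected)
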