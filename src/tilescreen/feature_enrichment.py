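"""Block-resampling interval enrichment, blacklist construction, peak rules.

Significance of intersection between a focal interval set (the deletions)
and a genomic feature set is assessed against matched null sets: the focal
intervals are partitioned into fixed-length blocks (default 500 kb) that
are independently relocated uniformly over the blacklist-free genome,
preserving within-block structure. Empirical enrichment/depletion p-values
count null sets with strictly greater/lower intersection than observed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    as_interval_frame,
    intersection_bp,
    merge_intervals,
    subtract_intervals,
)


# ---------------------------------------------------------------------------
# blacklist
# ---------------------------------------------------------------------------

def build_blacklist(
    genome, k: int = 50, min_run: int = 1000, numts=None
) -> pd.DataFrame:
    """Low-mappability runs plus optional NUMT intervals.

    A position is non-unique when its k-mer (canonicalized over strands)
    occurs more than once genome-wide. Bases covered by any non-unique
    k-mer are merged into runs, and runs of at least ``min_run`` bp are kept
    and merged with the NUMT set.
    """
    seqs = genome.sequences if hasattr(genome, "sequences") else dict(genome)
    comp = str.maketrans("ACGTN", "TGCAN")
    for chrom, seq in seqs.items():
        if k > len(seq):
            raise ValueError(f"k={k} exceeds length of {chrom}")
    counts: dict = {}
    per_chrom_kmers = {}
    for chrom, seq in seqs.items():
        s = seq.upper()
        kmers = []
        for i in range(len(s) - k + 1):
            km = s[i:i + k]
            rc = km.translate(comp)[::-1]
            canon = km if km <= rc else rc
            kmers.append(canon)
            counts[canon] = counts.get(canon, 0) + 1
        per_chrom_kmers[chrom] = kmers
    runs = []
    for chrom, kmers in per_chrom_kmers.items():
        nonunique = np.array([counts[km] > 1 for km in kmers], dtype=bool)
        if not nonunique.any():
            continue
        idx = np.flatnonzero(nonunique)
        # bases covered by a non-unique k-mer: [i, i + k)
        cover = [(chrom, int(i), int(i) + k) for i in idx]
        merged = merge_intervals(as_interval_frame(cover))
        long_enough = merged[(merged["end"] - merged["start"]) >= min_run]
        runs.append(long_enough)
    out = pd.concat(runs) if runs else pd.DataFrame(columns=["chrom", "start", "end"])
    if numts is not None and len(numts):
        out = pd.concat([out, as_interval_frame(numts)])
    return merge_intervals(out).reset_index(drop=True)


# ---------------------------------------------------------------------------
# block resampling
# ---------------------------------------------------------------------------

@dataclass
class BlockConfig:
    block_length: int = 500_000
    n_sets: int = 1000
    within_chromosome: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.block_length <= 0:
            raise ValueError("block length must be positive")
        if self.n_sets < 100:
            raise ValueError("need >= 100 null sets")


def block_resample(
    features, genome_sizes: dict, blacklist=None, cfg: BlockConfig | None = None
) -> list:
    """Sample matched null interval sets by block relocation.

    Features are merged, partitioned into blocks of ``block_length`` by
    their start coordinate (within-block offsets preserved), and each block
    is relocated uniformly over positions where the whole block fits inside
    one blacklist-free segment (across chromosomes unless
    ``within_chromosome``). Relocated features overlapping the blacklist or
    a chromosome end are dropped. Returns ``n_sets`` interval frames.
    """
    cfg = cfg or BlockConfig()
    rng = np.random.default_rng(cfg.seed)
    feats = merge_intervals(features)
    blk = merge_intervals(blacklist) if blacklist is not None else pd.DataFrame(
        columns=["chrom", "start", "end"]
    )
    universe = as_interval_frame(
        [(c, 0, size) for c, size in genome_sizes.items()]
    )
    eligible = subtract_intervals(universe, blk)
    L = cfg.block_length

    # eligible segments able to host a full block
    seg = eligible[(eligible["end"] - eligible["start"]) >= 1].reset_index(drop=True)

    def segments_for(chrom=None):
        s = seg if chrom is None else seg[seg["chrom"] == chrom]
        room = (s["end"] - s["start"] - L + 1).clip(lower=0).to_numpy()
        if room.sum() <= 0:
            raise ValueError("eligible genome shorter than the block length")
        return s.reset_index(drop=True), room

    # partition features into blocks
    blocks = []
    for (chrom, bidx), sub in feats.assign(_b=feats["start"] // L).groupby(
        ["chrom", "_b"]
    ):
        origin = bidx * L
        offs = [
            (int(s - origin), int(e - origin)) for s, e in zip(sub["start"], sub["end"])
        ]
        blocks.append((chrom, offs))

    null_sets = []
    for _ in range(cfg.n_sets):
        rows = []
        for chrom, offs in blocks:
            s, room = segments_for(chrom if cfg.within_chromosome else None)
            probs = room / room.sum()
            si = rng.choice(len(s), p=probs)
            pos = int(s.loc[si, "start"] + rng.integers(0, room[si]))
            new_chrom = s.loc[si, "chrom"]
            size = genome_sizes[new_chrom]
            for off_s, off_e in offs:
                ns, ne = pos + off_s, pos + off_e
                if ns < 0 or ne > size:
                    continue  # drop: falls off the chromosome
                piece = pd.DataFrame(
                    [(new_chrom, ns, ne)], columns=["chrom", "start", "end"]
                )
                if len(blk) and intersection_bp(piece, blk) > 0:
                    continue  # drop policy
                rows.append((new_chrom, ns, ne))
        null_sets.append(
            pd.DataFrame(rows, columns=["chrom", "start", "end"])
        )
    return null_sets


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    feature_set: str
    observed_bp: int
    null_bp: np.ndarray
    p_enrich: float
    p_deplete: float
    n_sets: int
    p_enrich_label: str = ""
    p_deplete_label: str = ""


def empirical_enrichment(
    observed_bp: int, null_bp, feature_set: str = ""
) -> EnrichmentResult:
    """Strict-count empirical p-values against the null intersections.

    p_enrich counts null sets with intersection strictly greater than
    observed; p_deplete strictly lower. Zero counts are reported as
    "< 1/n_sets" rather than 0.
    """
    null_bp = np.asarray(null_bp)
    n = len(null_bp)
    if n < 100:
        raise ValueError("need >= 100 null sets")
    p_enrich = float((null_bp > observed_bp).sum()) / n
    p_deplete = float((null_bp < observed_bp).sum()) / n

    def label(p):
        return f"< {1 / n:g}" if p == 0 else f"{p:g}"

    return EnrichmentResult(
        feature_set, int(observed_bp), null_bp, p_enrich, p_deplete, n,
        p_enrich_label=label(p_enrich), p_deplete_label=label(p_deplete),
    )


def enrichment_test(
    focal, feature_sets: dict, genome_sizes: dict, blacklist=None,
    cfg: BlockConfig | None = None,
) -> pd.DataFrame:
    """Full resampling test of a focal set against named feature sets."""
    nulls = block_resample(focal, genome_sizes, blacklist, cfg)
    rows = []
    for name, fs in feature_sets.items():
        obs = intersection_bp(focal, fs)
        null_bp = np.array([intersection_bp(ns, fs) for ns in nulls])
        r = empirical_enrichment(obs, null_bp, name)
        rows.append((
            name, r.observed_bp, float(null_bp.mean()), float(null_bp.std(ddof=1)),
            r.p_enrich, r.p_deplete, r.p_enrich_label, r.p_deplete_label, r.n_sets,
        ))
    return pd.DataFrame(rows, columns=[
        "feature_set", "observed_bp", "null_mean_bp", "null_sd_bp",
        "p_enrich", "p_deplete", "p_enrich_label", "p_deplete_label", "n_sets",
    ])


# ---------------------------------------------------------------------------
# peak intersection rule
# ---------------------------------------------------------------------------

def peak_hdel_intersections(peaks, hdels) -> tuple:
    """Half-overlap rule: a peak counts iff >= half its length overlaps a hDel.

    Returns (per-peak frame with a ``qualifies`` flag and best hDel, per-hDel
    boolean flag of having any qualifying peak).
    """
    pk = as_interval_frame(peaks).reset_index(drop=True)
    hd = hdels.reset_index(drop=True)
    qualifies = np.zeros(len(pk), dtype=bool)
    best = np.array([""] * len(pk), dtype=object)
    hdel_flag = pd.Series(False, index=hd["name"] if "name" in hd else hd.index)
    for i, p in pk.iterrows():
        plen = p["end"] - p["start"]
        for _, h in hd[hd["chrom"] == p["chrom"]].iterrows():
            ov = min(p["end"], h["end"]) - max(p["start"], h["start"])
            if ov >= 0.5 * plen and ov > 0:
                qualifies[i] = True
                best[i] = h["name"] if "name" in h else ""
                hdel_flag.loc[best[i]] = True
                break
    out = pk.copy()
    out["qualifies"] = qualifies
    out["hdel"] = best
    return out, hdel_flag
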