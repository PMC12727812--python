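"""Tiling sgRNA library design against deletion intervals.

Candidate guides are GN19 spacers (genomic 20-mer with the 5' base forced to
G for U6 transcription) adjacent to an NGG PAM, enumerated on both strands
inside each target interval. Candidates are filtered on exact-match and
mismatch off-target burden plus forbidden motifs, grouped into fixed 50-bp
genomic bins, and selected by a three-stage policy: best-per-bin, then
sequentially deeper ranks per bin for under-covered targets, then flank
rescue.

Candidate tables are pandas DataFrames with one row per guide; a frozen
:class:`GuideRecord` view is available for single-guide work.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGTN", "TGCAN")

GUIDE_COLUMNS = [
    "id", "spacer", "chrom", "start", "end", "strand", "pam",
    "hdel_id", "flank", "bin",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA: GN19 spacer plus its genomic protospacer context."""

    id: str
    spacer: str
    chrom: str
    start: int  # protospacer start, 0-based
    end: int  # protospacer end (start + 20)
    strand: str
    pam: str
    hdel_id: str = ""
    bin: int = -1
    score: float = float("nan")
    perfect_matches: int = -1
    specificity: float = float("nan")
    max_offtarget_activity: float = float("nan")
    homopolymers: tuple = ()

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        if self.spacer[0] != "G":
            raise ValueError("spacer must start with G")


@dataclass
class FilterRules:
    """Off-target and motif exclusion thresholds."""

    max_perfect_matches: int = 1
    min_specificity: float = 0.2
    max_offtarget_activity: float = 0.8
    forbidden_motifs: tuple = ("TTTT",)


@dataclass
class SelectionPolicy:
    """Tiling selection policy parameters."""

    bin_size: int = 50
    min_guides_per_target: int = 10
    flank_extent: int = 250
    flank_min_guides: int = 5
    scorer: str = "hash"

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.min_guides_per_target < 1 or self.flank_min_guides < 1:
            raise ValueError("selection minima must be >= 1")


def _sequences(genome) -> dict:
    return genome.sequences if hasattr(genome, "sequences") else dict(genome)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def enumerate_candidates(genome, targets, flank: bool = False) -> pd.DataFrame:
    """Enumerate GN19-NGG candidates whose protospacer lies within a target.

    Both strands are scanned. The PAM may extend past the target boundary
    but not past the chromosome. Spacer = genomic 20-mer (reverse
    complemented on the minus strand) with the first base replaced by G.
    """
    seqs = _sequences(genome)
    if isinstance(targets, pd.DataFrame):
        tgt = targets
    else:
        tgt = pd.DataFrame(
            [(t.chrom, t.start, t.end, getattr(t, "name", f"target_{i}"))
             for i, t in enumerate(targets)],
            columns=["chrom", "start", "end", "name"],
        )
    rows = []
    for _, t in tgt.iterrows():
        if t["chrom"] not in seqs:
            raise KeyError(f"target chromosome {t['chrom']!r} absent from genome")
        seq = seqs[t["chrom"]].upper()
        name = t.get("name", "")
        for i in range(int(t["start"]), int(t["end"]) - 19):
            # + strand: protospacer [i, i+20), PAM [i+20, i+23) = NGG
            if i + 23 <= len(seq) and seq[i + 21] == "G" and seq[i + 22] == "G":
                proto = seq[i:i + 20]
                rows.append((
                    f"{name}_{t['chrom']}:{i}:+", "G" + proto[1:], t["chrom"],
                    i, i + 20, "+", seq[i + 20:i + 23], name, flank, -1,
                ))
            # - strand: CCN at [i-3, i), protospacer genomic [i, i+20)
            if i - 3 >= 0 and seq[i - 3] == "C" and seq[i - 2] == "C":
                proto = revcomp(seq[i:i + 20])
                rows.append((
                    f"{name}_{t['chrom']}:{i}:-", "G" + proto[1:], t["chrom"],
                    i, i + 20, "-", revcomp(seq[i - 3:i]), name, flank, -1,
                ))
    return pd.DataFrame(rows, columns=GUIDE_COLUMNS)


# ---------------------------------------------------------------------------
# off-target scoring
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


class OffTargetIndex:
    """All NGG-adjacent 20-mer protospacer sites of a genome, both strands.

    Matching is done on the 19-nt variable region (spacer positions 2-20):
    the forced 5' G means the guide's own site must count as a perfect match
    even when the genomic base there is not G.
    """

    def __init__(self, genome):
        windows, coords = [], []
        for chrom, seq in _sequences(genome).items():
            s = seq.upper()
            arr = _encode(s)
            n = len(arr)
            if n < 23:
                continue
            # + strand: seq[i+21] == G and seq[i+22] == G
            g = arr == ord("G")
            plus = np.flatnonzero(g[21:n - 1] & g[22:n]) if n >= 23 else []
            for i in plus:
                windows.append(arr[i:i + 20])
                coords.append((chrom, int(i), "+"))
            c = arr == ord("C")
            minus = np.flatnonzero(c[:-22] & c[1:-21]) if n >= 23 else []
            for i in minus:
                win = _encode(revcomp(s[i + 3:i + 23]))
                windows.append(win)
                coords.append((chrom, int(i + 3), "-"))
        self.windows = (
            np.vstack(windows) if windows else np.empty((0, 20), dtype=np.uint8)
        )
        self.coords = pd.DataFrame(coords, columns=["chrom", "start", "strand"])

    def mismatches(self, spacer: str) -> np.ndarray:
        """Per-site mismatch count over the 19-nt variable region."""
        q = _encode(spacer)[1:]
        if not len(self.windows):
            return np.empty(0, dtype=int)
        return (self.windows[:, 1:] != q[None, :]).sum(axis=1)


@dataclass
class OffTargetSummary:
    perfect_matches: int
    specificity_score: float
    max_offtarget_activity: float


def score_offtargets(record, index: OffTargetIndex, max_mismatch: int = 3) -> OffTargetSummary:
    """Exact-match counting plus a monotone mismatch-burden surrogate.

    perfect_matches counts genome sites matching the variable region + NGG.
    Specificity = 1 / (1 + sum over off-target sites with <= max_mismatch
    mismatches of 0.5**mm); predicted off-target activity = max over those
    sites of 0.5**mm. Both lie in [0, 1] and are monotone in off-target
    burden; a pluggable scorer can replace them behind the same fields.
    """
    mm = index.mismatches(record["spacer"] if isinstance(record, (dict, pd.Series)) else record.spacer)
    rec = record if isinstance(record, (dict, pd.Series)) else record.__dict__
    own = (
        (index.coords["chrom"] == rec["chrom"])
        & (index.coords["start"] == rec["start"])
        & (index.coords["strand"] == rec["strand"])
    ).to_numpy()
    perfect = int((mm == 0).sum())
    off = ~own & (mm <= max_mismatch)
    w = np.exp2(-mm[off].astype(float))
    specificity = 1.0 / (1.0 + w.sum())
    activity = float(w.max()) if w.size else 0.0
    return OffTargetSummary(perfect, float(specificity), activity)


def score_offtargets_table(candidates: pd.DataFrame, genome, max_mismatch: int = 3) -> pd.DataFrame:
    """Vectorized :func:`score_offtargets` over a candidate table."""
    index = OffTargetIndex(genome)
    out = candidates.copy()
    res = [
        score_offtargets(row, index, max_mismatch)
        for _, row in candidates.iterrows()
    ]
    out["perfect_matches"] = [r.perfect_matches for r in res]
    out["specificity"] = [r.specificity_score for r in res]
    out["max_offtarget_activity"] = [r.max_offtarget_activity for r in res]
    return out


# ---------------------------------------------------------------------------
# on-target scoring (pluggable)
# ---------------------------------------------------------------------------

def hash_score(spacer: str) -> float:
    """Deterministic distribution-free on-target score in [0, 1)."""
    digest = hashlib.md5(spacer.encode()).hexdigest()
    return int(digest[:12], 16) / 16**12


ON_TARGET_SCORERS = {"hash": hash_score}


def score_on_target(candidates: pd.DataFrame, scorer: str = "hash") -> pd.DataFrame:
    fn = ON_TARGET_SCORERS[scorer]
    out = candidates.copy()
    out["score"] = [fn(s) for s in out["spacer"]]
    return out


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_candidates(candidates: pd.DataFrame, rules: FilterRules | None = None):
    """Apply exclusion rules; returns (kept, rejected-with-reason)."""
    rules = rules or FilterRules()
    df = candidates
    reasons = pd.Series("", index=df.index)
    reject = pd.Series(False, index=df.index)

    def mark(mask, reason):
        nonlocal reject
        new = mask & ~reject
        reasons[new] = reason
        reject = reject | mask

    mark(df["perfect_matches"] > rules.max_perfect_matches, "multi_perfect_match")
    mark(df["specificity"] < rules.min_specificity, "low_specificity")
    mark(df["max_offtarget_activity"] > rules.max_offtarget_activity, "high_offtarget_activity")
    motif_hit = df["spacer"].apply(
        lambda s: any(m in s for m in rules.forbidden_motifs)
    )
    mark(motif_hit, "forbidden_motif")

    rejected = df[reject].copy()
    rejected["reason"] = reasons[reject]
    return df[~reject].copy(), rejected


# ---------------------------------------------------------------------------
# homopolymers
# ---------------------------------------------------------------------------

def annotate_homopolymers(spacer: str, min_run: int = 4) -> list:
    """Maximal single-base runs of length >= min_run; 1-based start positions."""
    runs = []
    i = 0
    while i < len(spacer):
        j = i
        while j < len(spacer) and spacer[j] == spacer[i]:
            j += 1
        if j - i >= min_run:
            runs.append((spacer[i], i + 1, j - i))
        i = j
    return runs


def homopolymer_string(spacer: str, min_run: int = 4) -> str:
    return ";".join(f"{b}:{s}:{l}" for b, s, l in annotate_homopolymers(spacer, min_run))


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def assign_bins(candidates: pd.DataFrame, bin_size: int = 50) -> pd.DataFrame:
    """Fixed bins from chromosome coordinate 0, keyed on protospacer start."""
    out = candidates.copy()
    out["bin"] = out["start"] // bin_size
    return out


def _ranked(df: pd.DataFrame) -> pd.DataFrame:
    """Within-bin rank with the deterministic tie-break (score desc, start
    asc, spacer lexicographic)."""
    df = df.sort_values(
        ["score", "start", "spacer"], ascending=[False, True, True], kind="mergesort"
    )
    df = df.copy()
    df["rank"] = df.groupby(["chrom", "bin"]).cumcount() + 1
    return df


@dataclass
class LibrarySelection:
    selected: pd.DataFrame  # candidate rows + stage column
    deficient: list = field(default_factory=list)  # hDel ids below minimum


def select_tiling_library(
    candidates: pd.DataFrame,
    policy: SelectionPolicy | None = None,
    flank_candidates: pd.DataFrame | None = None,
) -> LibrarySelection:
    """Three-stage tiling selection.

    Stage 1 takes the best-scoring candidate in each 50-bp bin of each
    target. Stage 2, for targets still below ``min_guides_per_target``,
    admits the 2nd-, then 3rd-, ... best candidate of every bin in lockstep
    until the minimum is met or candidates are exhausted. Stage 3 tops up
    remaining deficient targets from flank candidates until
    ``flank_min_guides`` total guides; targets still short are flagged.
    Selection depends only on (candidates, scores, policy).
    """
    policy = policy or SelectionPolicy()
    cols = list(candidates.columns) + ["stage"]
    if candidates.empty and (flank_candidates is None or flank_candidates.empty):
        return LibrarySelection(pd.DataFrame(columns=cols))

    cand = assign_bins(candidates, policy.bin_size)
    if "score" not in cand or cand["score"].isna().any():
        cand = score_on_target(cand, policy.scorer)
    ranked = _ranked(cand)

    picked = []
    deficient = []
    hdel_ids = sorted(set(cand["hdel_id"]) | (
        set(flank_candidates["hdel_id"]) if flank_candidates is not None else set()
    ))
    flank = None
    if flank_candidates is not None and len(flank_candidates):
        flank = assign_bins(flank_candidates, policy.bin_size)
        if "score" not in flank or flank["score"].isna().any():
            flank = score_on_target(flank, policy.scorer)
        flank = _ranked(flank)

    for hdel in hdel_ids:
        sub = ranked[ranked["hdel_id"] == hdel]
        take = sub[sub["rank"] == 1].copy()
        take["stage"] = 1
        r = 2
        while len(take) < policy.min_guides_per_target:
            nxt = sub[sub["rank"] == r]
            if nxt.empty:
                break
            nxt = nxt.copy()
            nxt["stage"] = 2
            take = nxt if take.empty else pd.concat([take, nxt])
            r += 1
        if len(take) < policy.min_guides_per_target:
            # flank rescue toward the lower flank minimum
            if flank is not None:
                fsub = flank[flank["hdel_id"] == hdel].sort_values(
                    ["rank", "score", "start", "spacer"],
                    ascending=[True, False, True, True], kind="mergesort",
                )
                need = policy.flank_min_guides - len(take)
                if need > 0 and len(fsub):
                    add = fsub.head(need).copy()
                    add["stage"] = 3
                    take = add if take.empty else pd.concat([take, add])
            if len(take) < policy.flank_min_guides:
                deficient.append(hdel)
        picked.append(take)

    selected = pd.concat(picked).drop(columns=["rank"]).reset_index(drop=True)
    return LibrarySelection(selected=selected, deficient=deficient)


# ---------------------------------------------------------------------------
# non-targeting controls and manifest assembly
# ---------------------------------------------------------------------------

def make_nontargeting(genome, n: int, seed: int = 0, max_tries: int = 100_000) -> pd.DataFrame:
    """Random GN19 spacers with zero perfect-match genomic target sites."""
    rng = np.random.default_rng(seed)
    index = OffTargetIndex(genome)
    rows, seen = [], set()
    tries = 0
    while len(rows) < n and tries < max_tries:
        tries += 1
        spacer = "G" + "".join(rng.choice(list("ACGT"), size=19))
        if spacer in seen:
            continue
        if int((index.mismatches(spacer) == 0).sum()) == 0:
            seen.add(spacer)
            rows.append((f"non-targeting_{len(rows):05d}", spacer))
    if len(rows) < n:
        raise RuntimeError("could not generate enough non-targeting spacers")
    df = pd.DataFrame(rows, columns=["id", "spacer"])
    df["category"] = "non-targeting"
    return df


CATEGORIES = (
    "hdel", "flank", "non-targeting", "essential",
    "proliferation-suppressor", "expressed-gene", "TSS", "putative-CRE",
)


def assemble_manifest(components: dict) -> pd.DataFrame:
    """Concatenate named component tables into one screen manifest.

    Each component is a DataFrame with at least id and spacer columns;
    a ``category`` column is added from the component name when missing.
    Duplicate ids or spacers across components are an error.
    """
    parts = []
    for name, df in components.items():
        if df is None or len(df) == 0:
            continue
        part = df.copy()
        if "category" not in part:
            part["category"] = name
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=["id", "spacer", "category"])
    manifest = pd.concat(parts, ignore_index=True)
    if manifest["id"].duplicated().any():
        dup = manifest.loc[manifest["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"duplicate sgRNA id across components: {dup}")
    if manifest["spacer"].duplicated().any():
        dup = manifest.loc[manifest["spacer"].duplicated(), "spacer"].iloc[0]
        raise ValueError(f"duplicate spacer across components: {dup}")
    if "homopolymers" not in manifest:
        manifest["homopolymers"] = manifest["spacer"].map(homopolymer_string)
    return manifest
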