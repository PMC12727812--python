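"""Genomic interval primitives.

All coordinates are 0-based half-open (BED convention). Interval sets are
pandas DataFrames with at least ``chrom``, ``start``, ``end`` columns; a
``name`` column is carried through where present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

INTERVAL_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True)
class GenomicInterval:
    """One 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def as_interval_frame(intervals) -> pd.DataFrame:
    """Coerce a list of GenomicInterval / (chrom, start, end) tuples / DataFrame
    into a canonical interval frame."""
    if isinstance(intervals, pd.DataFrame):
        df = intervals.copy()
    else:
        rows = []
        for iv in intervals:
            if isinstance(iv, GenomicInterval):
                rows.append((iv.chrom, iv.start, iv.end))
            else:
                rows.append(tuple(iv[:3]))
        df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    bad = df["start"] >= df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"interval row {i}: start >= end")
    return df


def merge_intervals(intervals) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome (bedtools merge)."""
    df = as_interval_frame(intervals)
    if df.empty:
        return df
    out = []
    for chrom, sub in df.sort_values(["chrom", "start"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)


def total_bp(intervals) -> int:
    df = merge_intervals(intervals)
    if df.empty:
        return 0
    return int((df["end"] - df["start"]).sum())


def intersection_bp(set_a, set_b) -> int:
    """Total overlap in bp between two interval sets, each merged first."""
    a = merge_intervals(set_a)
    b = merge_intervals(set_b)
    if a.empty or b.empty:
        return 0
    bp = 0
    for chrom, sub_a in a.groupby("chrom"):
        sub_b = b[b["chrom"] == chrom]
        if sub_b.empty:
            continue
        sa = sub_a["start"].to_numpy()
        ea = sub_a["end"].to_numpy()
        sb = sub_b["start"].to_numpy()
        eb = sub_b["end"].to_numpy()
        # both merged and sorted: sweep with broadcasting (sets are small)
        ov = np.minimum(ea[:, None], eb[None, :]) - np.maximum(sa[:, None], sb[None, :])
        bp += int(np.clip(ov, 0, None).sum())
    return bp


def overlap_lengths(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Per-query-row total overlap bp with the (merged) subject set."""
    sub = merge_intervals(subject)
    out = np.zeros(len(query), dtype=np.int64)
    for i, (chrom, s, e) in enumerate(
        zip(query["chrom"].to_numpy(), query["start"].to_numpy(), query["end"].to_numpy())
    ):
        m = sub[sub["chrom"] == chrom]
        if m.empty:
            continue
        ov = np.minimum(m["end"].to_numpy(), e) - np.maximum(m["start"].to_numpy(), s)
        out[i] = np.clip(ov, 0, None).sum()
    return out


def subtract_intervals(universe: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """universe minus mask, both merged; returns the remaining segments."""
    uni = merge_intervals(universe)
    msk = merge_intervals(mask)
    if msk.empty:
        return uni
    out = []
    for chrom, sub in uni.groupby("chrom"):
        holes = msk[msk["chrom"] == chrom]
        for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
            pos = s
            rel = holes[(holes["end"] > s) & (holes["start"] < e)]
            for hs, he in zip(rel["start"].to_numpy(), rel["end"].to_numpy()):
                if hs > pos:
                    out.append((chrom, pos, hs))
                pos = max(pos, he)
            if pos < e:
                out.append((chrom, pos, e))
    return pd.DataFrame(out, columns=INTERVAL_COLUMNS)
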