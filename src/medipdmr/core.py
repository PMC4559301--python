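"""Genomic-interval containers and interval-set arithmetic.

All coordinates are 0-based half-open (BED convention).  Interval
collections are carried as pandas DataFrames with at least the columns
``chrom``, ``start``, ``end`` ("interval frames"); single intervals are
:class:`GenomicInterval` instances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open region on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


def intervals_frame(records) -> pd.DataFrame:
    """Build an interval frame from GenomicIntervals or (chrom,start,end) tuples."""
    rows = []
    for r in records:
        if isinstance(r, GenomicInterval):
            rows.append((r.chrom, r.start, r.end))
        else:
            rows.append(tuple(r[:3]))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def validate_intervals(df: pd.DataFrame, what: str = "interval") -> None:
    """Raise ValueError naming the first malformed record (start >= end or start < 0)."""
    bad = df.index[(df["start"] >= df["end"]) | (df["start"] < 0)]
    if len(bad):
        row = df.loc[bad[0]]
        raise ValueError(
            f"malformed {what} at index {bad[0]}: "
            f"{row['chrom']}:{row['start']}-{row['end']}"
        )


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of an interval set: overlapping/adjacent intervals merged, sorted."""
    if df.empty:
        return df.loc[:, ["chrom", "start", "end"]].copy()
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
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def total_bases(df: pd.DataFrame) -> int:
    """Base-pair size of the union of an interval set."""
    m = merge_intervals(df)
    return int((m["end"] - m["start"]).sum()) if len(m) else 0


def _overlap_bases_sorted(a_s, a_e, b_s, b_e) -> int:
    """Overlap bases between two merged, sorted interval arrays on one chromosome."""
    if len(a_s) == 0 or len(b_s) == 0:
        return 0
    lo = np.searchsorted(b_e, a_s, side="right")
    hi = np.searchsorted(b_s, a_e, side="left")
    cum = np.concatenate([[0], np.cumsum(b_e - b_s)])
    full = cum[hi] - cum[lo]
    has = hi > lo
    first_clip = np.zeros(len(a_s), dtype=np.int64)
    last_clip = np.zeros(len(a_s), dtype=np.int64)
    idx = np.where(has)[0]
    # b is merged, so only the first/last overlapping b interval can stick out
    first_clip[idx] = np.maximum(0, a_s[idx] - b_s[lo[idx]])
    last_clip[idx] = np.maximum(0, b_e[hi[idx] - 1] - a_e[idx])
    return int((full - first_clip - last_clip).sum())


def overlap_bases(a: pd.DataFrame, b: pd.DataFrame) -> int:
    """Bases in the intersection of two interval sets (each merged first)."""
    am, bm = merge_intervals(a), merge_intervals(b)
    tot = 0
    for chrom, sub in am.groupby("chrom", sort=False):
        bsub = bm[bm["chrom"] == chrom]
        tot += _overlap_bases_sorted(
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            bsub["start"].to_numpy(np.int64),
            bsub["end"].to_numpy(np.int64),
        )
    return tot


def overlaps_any(query: pd.DataFrame, reference: pd.DataFrame) -> np.ndarray:
    """Boolean per query row: does it overlap (>= 1 bp) any reference interval?"""
    ref = merge_intervals(reference)
    out = np.zeros(len(query), dtype=bool)
    for chrom, rsub in ref.groupby("chrom", sort=False):
        mask = (query["chrom"] == chrom).to_numpy()
        if not mask.any():
            continue
        qs = query.loc[mask, "start"].to_numpy(np.int64)
        qe = query.loc[mask, "end"].to_numpy(np.int64)
        rs = rsub["start"].to_numpy(np.int64)
        re_ = rsub["end"].to_numpy(np.int64)
        lo = np.searchsorted(re_, qs, side="right")
        hi = np.searchsorted(rs, qe, side="left")
        out[mask] = hi > lo
    return out


def frame_midpoints(df: pd.DataFrame) -> pd.Series:
    return (df["start"] + df["end"]) // 2
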