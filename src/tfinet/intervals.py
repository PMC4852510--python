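"""Minimal interval engine for 0-based half-open genomic intervals.

Two intervals [a, b) and [c, d) overlap iff a < d and c < b. Counting is
done per chromosome with sorted endpoint arrays, so a query over m regions
against n reads costs O((n + m) log n) — ample for desk-scale tracks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def count_overlaps(regions: pd.DataFrame, reads: pd.DataFrame) -> np.ndarray:
    """Count, for every region, how many read intervals overlap it.

    A read counts once per region it overlaps (any-overlap, no fractional
    assignment). Both frames need chrom/start/end columns.
    """
    counts = np.zeros(len(regions), dtype=np.int64)
    by_chrom = {c: g for c, g in reads.groupby("chrom", sort=False)}
    for chrom, idx in regions.groupby("chrom", sort=False).groups.items():
        sub = by_chrom.get(chrom)
        if sub is None:
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = np.sort(sub["end"].to_numpy())
        pos = regions.index.get_indexer(idx)
        rs = regions["start"].to_numpy()[pos]
        re = regions["end"].to_numpy()[pos]
        # overlap iff read.start < region.end and read.end > region.start
        n_start_before_end = np.searchsorted(starts, re, side="left")
        n_end_before_start = np.searchsorted(ends, rs, side="right")
        counts[pos] = n_start_before_end - n_end_before_start
    return counts


def to_one_based_closed(df: pd.DataFrame) -> pd.DataFrame:
    """Convert 0-based half-open start/end to 1-based closed (GFF-style)."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out


def to_zero_based_half_open(df: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_one_based_closed`."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return out


def overlap_pairs(a: pd.DataFrame, b: pd.DataFrame) -> list[tuple[int, int]]:
    """All (positional index in a, positional index in b) overlapping pairs.

    Sort-merge sweep per chromosome; used for peak-to-domain assignment.
    """
    pairs: list[tuple[int, int]] = []
    a_pos = np.arange(len(a))
    b_pos = np.arange(len(b))
    bj = {c: (b_pos[b.index.get_indexer(loc)], b.loc[loc, "start"].to_numpy(), b.loc[loc, "end"].to_numpy())
          for c, loc in b.groupby("chrom", sort=False).groups.items()}
    for chrom, loc in a.groupby("chrom", sort=False).groups.items():
        if chrom not in bj:
            continue
        bpos, bs, be = bj[chrom]
        order = np.argsort(bs, kind="stable")
        bpos, bs, be = bpos[order], bs[order], be[order]
        apos = a_pos[a.index.get_indexer(loc)]
        as_ = a.loc[loc, "start"].to_numpy()
        ae = a.loc[loc, "end"].to_numpy()
        for i, s, e in zip(apos, as_, ae):
            # candidates: b.start < a.end; then check b.end > a.start
            hi = np.searchsorted(bs, e, side="left")
            hits = np.nonzero(be[:hi] > s)[0]
            pairs.extend((int(i), int(bpos[h])) for h in hits)
    return pairs
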