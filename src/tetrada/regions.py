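"""Interval utilities on 0-based half-open coordinates.

A "mask" is a DataFrame with columns chrom/start/end describing the regions
eligible for an operation (typically the non-peri-centromeric chromosome
arms).  Background sampling for every permutation test goes through the
helpers here, so the mask is respected exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MASK_COLUMNS = ["chrom", "start", "end"]


def merge_intervals(df: pd.DataFrame, pad: int = 0) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals, optionally padded by ``pad`` bp."""
    if df is None or len(df) == 0:
        return pd.DataFrame(columns=MASK_COLUMNS)
    out = []
    for chrom, grp in df.groupby("chrom", sort=True):
        starts = np.maximum(grp["start"].to_numpy() - pad, 0)
        ends = grp["end"].to_numpy() + pad
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=MASK_COLUMNS)


def positions_within(
    chroms: np.ndarray, positions: np.ndarray, intervals: pd.DataFrame, pad: int = 0
) -> np.ndarray:
    """Boolean mask: does each (chrom, pos) fall within ``pad`` bp of an interval?"""
    hit = np.zeros(len(positions), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    merged = merge_intervals(intervals, pad=pad)
    for chrom, grp in merged.groupby("chrom"):
        sel = chroms == chrom
        if not sel.any():
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        pos = positions[sel]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] < ends[idx[ok]]
        hit[np.flatnonzero(sel)] = ok
    return hit


def complement(intervals: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    """Complement of ``intervals`` within the chromosomes of ``chrom_sizes``."""
    merged = merge_intervals(intervals)
    out = []
    for chrom, size in chrom_sizes.items():
        grp = merged[merged["chrom"] == chrom]
        prev = 0
        for _, row in grp.iterrows():
            if row["start"] > prev:
                out.append((chrom, prev, min(row["start"], size)))
            prev = max(prev, row["end"])
        if prev < size:
            out.append((chrom, prev, size))
    return pd.DataFrame(out, columns=MASK_COLUMNS)


def clip_to_chrom(df: pd.DataFrame, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    df = df.copy()
    sizes = df["chrom"].map(chrom_sizes)
    df["start"] = np.maximum(df["start"], 0)
    df["end"] = np.minimum(df["end"], sizes)
    return df[df["end"] > df["start"]].reset_index(drop=True)


def mask_length(mask: pd.DataFrame) -> int:
    return int((mask["end"] - mask["start"]).sum())


def sample_positions(mask: pd.DataFrame, n: int, rng: np.random.Generator):
    """Draw ``n`` positions uniformly over the mask.

    Returns (chroms, positions) arrays.
    """
    lens = (mask["end"] - mask["start"]).to_numpy(dtype=np.int64)
    if lens.sum() <= 0:
        raise ValueError("empty mask")
    idx = rng.choice(len(mask), size=n, p=lens / lens.sum())
    offs = (rng.random(n) * lens[idx]).astype(np.int64)
    chroms = mask["chrom"].to_numpy()[idx]
    pos = mask["start"].to_numpy()[idx] + offs
    return chroms, pos


def sample_intervals(mask: pd.DataFrame, lengths: np.ndarray, rng: np.random.Generator):
    """Draw intervals of the given lengths, each fully inside one mask interval.

    Interval choice is weighted by the room left for the tract (rejection-free
    equivalent of uniform placement conditioned on fitting).  Raises if a
    length exceeds every mask interval.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    m_start = mask["start"].to_numpy(dtype=np.int64)
    m_len = (mask["end"] - mask["start"]).to_numpy(dtype=np.int64)
    m_chrom = mask["chrom"].to_numpy()
    chroms = np.empty(len(lengths), dtype=object)
    starts = np.empty(len(lengths), dtype=np.int64)
    for L in np.unique(lengths):
        sel = lengths == L
        room = m_len - L  # admissible starts per interval = room + 1 (if >= 0)
        w = np.where(room >= 0, room + 1, 0).astype(float)
        if w.sum() <= 0:
            raise ValueError(f"tract length {L} exceeds every mask interval")
        idx = rng.choice(len(mask), size=sel.sum(), p=w / w.sum())
        offs = (rng.random(sel.sum()) * (room[idx] + 1)).astype(np.int64)
        chroms[sel] = m_chrom[idx]
        starts[sel] = m_start[idx] + offs
    return chroms, starts, starts + lengths
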