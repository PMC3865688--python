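"""Conversion-tract length inference by Monte-Carlo placement.

Observed conversion tracts are short relative to marker spacing, so the
tract length cannot be read off directly.  Instead, sets of tracts of a
fixed candidate length are placed uniformly on the non-peri-centromeric
marker landscape many times; the candidate whose simulated mean number of
converted markers (total over all tracts, and per converting tract) matches
the observed statistics is the length estimate.  The same machinery scans
scenarios for NCO tracts, where the true number of events per meiosis is
unknown and is swept over a grid of DSB counts (half assumed restored to
the original allele).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tetrada._random import as_rng
from tetrada.regions import sample_intervals


@dataclass
class TractSimResult:
    length_bp: int
    n_tracts: int
    n_reps: int
    mean_total: float
    sd_total: float
    mean_per_tract: float  # over tracts converting >= 1 marker
    sd_per_tract: float
    frac_converting: float


def _positions_by_chrom(markers: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in markers.groupby("chrom")
    }


def place_tracts(
    markers: pd.DataFrame,
    mask: pd.DataFrame,
    n_tracts: int,
    length_bp: int,
    n_reps: int,
    rng,
) -> TractSimResult:
    """Place ``n_tracts`` tracts of ``length_bp`` uniformly in the mask,
    ``n_reps`` times, counting markers overlapped by each tract.

    Tracts are kept fully inside one mask interval.  Raises when the length
    exceeds every mask interval.
    """
    if length_bp < 1:
        raise ValueError("tract length must be >= 1 bp")
    rng = as_rng(rng)
    if n_tracts == 0:
        return TractSimResult(length_bp, 0, n_reps, 0.0, 0.0, 0.0, 0.0, 0.0)
    pos = _positions_by_chrom(markers)
    total = n_reps * n_tracts
    chroms, starts, ends = sample_intervals(
        mask, np.full(total, length_bp, dtype=np.int64), rng
    )
    counts = np.zeros(total, dtype=np.int64)
    for chrom, p in pos.items():
        sel = chroms == chrom
        if not sel.any():
            continue
        counts[sel] = np.searchsorted(p, ends[sel]) - np.searchsorted(p, starts[sel])
    counts = counts.reshape(n_reps, n_tracts)
    totals = counts.sum(axis=1)
    converting = counts > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        per_tract = np.where(
            converting.sum(axis=1) > 0,
            counts.sum(axis=1) / np.maximum(converting.sum(axis=1), 1),
            np.nan,
        )
    return TractSimResult(
        length_bp=int(length_bp),
        n_tracts=int(n_tracts),
        n_reps=int(n_reps),
        mean_total=float(totals.mean()),
        sd_total=float(totals.std(ddof=1)) if n_reps > 1 else 0.0,
        mean_per_tract=float(np.nanmean(per_tract)),
        sd_per_tract=float(np.nanstd(per_tract, ddof=1)) if n_reps > 1 else 0.0,
        frac_converting=float(converting.mean()),
    )


def tract_length_grid(
    markers: pd.DataFrame,
    mask: pd.DataFrame,
    n_tracts: int,
    lengths: np.ndarray,
    n_reps: int,
    rng,
) -> pd.DataFrame:
    """Run :func:`place_tracts` over a grid of candidate lengths."""
    rng = as_rng(rng)
    rows = [
        place_tracts(markers, mask, n_tracts, int(L), n_reps, rng) for L in lengths
    ]
    return pd.DataFrame([r.__dict__ for r in rows])


def _invert_monotone(grid_x: np.ndarray, grid_y: np.ndarray, observed: float) -> float:
    """Linear interpolation of x at observed y (y assumed increasing in x)."""
    order = np.argsort(grid_x)
    x, y = np.asarray(grid_x, float)[order], np.asarray(grid_y, float)[order]
    if observed < y.min():
        raise ValueError(
            f"observed value {observed} below the simulated range "
            f"({y.min():.3g}); extend the grid to shorter lengths"
        )
    if observed > y.max():
        raise ValueError(
            f"observed value {observed} above the simulated range "
            f"({y.max():.3g}); extend the grid to longer lengths"
        )
    # y may be only approximately monotone (Monte-Carlo noise); use the
    # cumulative max to keep the inversion well defined
    y_mono = np.maximum.accumulate(y)
    return float(np.interp(observed, y_mono, x))


def estimate_coct_length(
    observed_total: float,
    observed_per_tract: float,
    grid: pd.DataFrame,
) -> dict:
    """Tract-length estimate from the simulated grid.

    Inverts both summary curves (total converted markers, and mean
    converted markers per converting tract) at the observed values; the
    returned interval spans the two point estimates, mirroring how the two
    statistics bracket the underlying length.
    """
    L_total = _invert_monotone(
        grid["length_bp"].to_numpy(), grid["mean_total"].to_numpy(), observed_total
    )
    L_per = _invert_monotone(
        grid["length_bp"].to_numpy(), grid["mean_per_tract"].to_numpy(),
        observed_per_tract,
    )
    return {
        "length_from_total": L_total,
        "length_from_per_tract": L_per,
        "interval": (min(L_total, L_per), max(L_total, L_per)),
    }


def nco_scenario_scan(
    markers: pd.DataFrame,
    mask: pd.DataFrame,
    dsb_grid,
    length_grid,
    n_meioses: int,
    n_reps: int,
    rng,
    frac_restored: float = 0.5,
) -> pd.DataFrame:
    """Expected converted markers per (DSB count, tract length) scenario.

    Each meiosis contributes ``dsb * (1 - frac_restored)`` potential NCO
    tracts; the reported totals cover all ``n_meioses`` meioses, and the
    per-tract mean covers tracts that overlap at least one marker, matching
    the two-panel comparison of observed vs simulated conversion counts.
    """
    rng = as_rng(rng)
    rows = []
    for dsb in dsb_grid:
        n_tracts = int(round(dsb * (1.0 - frac_restored))) * int(n_meioses)
        for L in length_grid:
            r = place_tracts(markers, mask, n_tracts, int(L), n_reps, rng)
            rows.append(
                {
                    "dsb_per_meiosis": int(dsb),
                    "length_bp": int(L),
                    "n_tracts": n_tracts,
                    "mean_total": r.mean_total,
                    "sd_total": r.sd_total,
                    "mean_per_tract": r.mean_per_tract,
                    "sd_per_tract": r.sd_per_tract,
                }
            )
    return pd.DataFrame(rows)


def expected_total_converted(
    markers: pd.DataFrame, mask: pd.DataFrame, n_tracts: int, length_bp: int
) -> float:
    """Exact E[total converted markers] under uniform placement.

    Brute-force integration oracle: for every marker, the probability that
    a single uniformly placed tract (kept inside one mask interval) covers
    it equals the number of admissible start positions covering the marker
    divided by all admissible starts.
    """
    m_start = mask["start"].to_numpy(dtype=np.int64)
    m_end = mask["end"].to_numpy(dtype=np.int64)
    m_chrom = mask["chrom"].to_numpy()
    room = m_end - m_start - length_bp
    starts_per = np.where(room >= 0, room + 1, 0)
    total_starts = float(starts_per.sum())
    if total_starts <= 0:
        raise ValueError("tract length exceeds every mask interval")
    p_cover = 0.0
    for chrom, grp in markers.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        for s, e, k, c in zip(m_start, m_end, starts_per, m_chrom):
            if c != chrom or k <= 0:
                continue
            inside = pos[(pos >= s) & (pos < e)]
            # admissible starts covering marker at p: max(s, p-L+1) .. min(p, e-L)
            lo = np.maximum(s, inside - length_bp + 1)
            hi = np.minimum(inside, e - length_bp)
            p_cover += np.maximum(hi - lo + 1, 0).sum() / total_starts
    return n_tracts * p_cover
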