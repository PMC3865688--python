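"""Association statistics between recombination sites and genomic context.

All permutation tests use the add-one estimator
``p = (1 + #{null as extreme as observed}) / (n_iter + 1)``
and are reproducible given a Generator or seed.  Background sampling always
goes through the supplied mask (typically the non-peri-centromeric arms).

The interference test follows the tetrad-label randomization idea: event
positions are kept fixed (preserving the inhomogeneous placement of
recombination along chromosomes) while the tetrad labels are reassigned
uniformly, which destroys within-meiosis dependence only.
"""

from __future__ import annotations

import itertools
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tetrada._random import as_rng
from tetrada.regions import sample_intervals, sample_positions


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    direction: str
    n_iter: int


def _perm_p(null: np.ndarray, observed: float, direction: str) -> float:
    if direction == "greater":
        k = int((null >= observed).sum())
    elif direction == "less":
        k = int((null <= observed).sum())
    elif direction == "two-sided":
        hi = (null >= observed).sum()
        lo = (null <= observed).sum()
        return min(1.0, 2.0 * (1 + min(hi, lo)) / (len(null) + 1))
    else:
        raise ValueError(direction)
    return (1 + k) / (len(null) + 1)


# ---------------------------------------------------------------------------
# crossover interference


def _co_co_stat(pos_by_chrom, labels_by_chrom):
    """Mean distance between adjacent same-tetrad events, pooled."""
    total, count = 0.0, 0
    for chrom, pos in pos_by_chrom.items():
        lab = labels_by_chrom[chrom]
        order = np.argsort(lab, kind="stable")  # pos already sorted per chrom
        pl, ll = pos[order], lab[order]
        same = ll[1:] == ll[:-1]
        d = pl[1:] - pl[:-1]
        total += d[same].sum()
        count += int(same.sum())
    return total / count if count else np.nan


def _co_nco_stat(co_pos, co_lab, nco_pos, nco_lab):
    """Mean distance from each NCO to the nearest same-tetrad CO (per chrom)."""
    dists = []
    for chrom in nco_pos:
        if chrom not in co_pos:
            continue
        cp, cl = co_pos[chrom], co_lab[chrom]
        for p, l in zip(nco_pos[chrom], nco_lab[chrom]):
            sel = cl == l
            if not sel.any():
                continue
            c = cp[sel]
            i = np.searchsorted(c, p)
            best = min(
                abs(p - c[i - 1]) if i > 0 else np.inf,
                abs(c[i] - p) if i < len(c) else np.inf,
            )
            dists.append(best)
    return float(np.mean(dists)) if dists else np.nan


def interference_test(
    events: pd.DataFrame,
    n_iter: int = 10_000,
    rng=None,
    pair: str = "co_co",
    direction: str = "greater",
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation test for interference between recombination events.

    ``events`` needs columns tetrad, chrom, pos and (for ``pair='co_nco'``)
    kind in {CO, NCO}.  The observed statistic is the mean distance between
    adjacent same-tetrad events (CO-CO) or from each NCO to its nearest
    same-tetrad CO; the null reassigns each event's tetrad label uniformly.
    ``exhaustive=True`` enumerates every label assignment instead of
    sampling (only feasible for toy inputs).
    """
    rng = as_rng(rng)
    ev = events.sort_values(["chrom", "pos"]).reset_index(drop=True)
    tetrad_codes, tetrad_index = pd.factorize(ev["tetrad"])
    n_tetrads = len(tetrad_index)
    if n_tetrads < 2:
        raise ValueError("need at least two tetrads")
    if pair == "co_co":
        sub = ev[ev.get("kind", "CO") == "CO"] if "kind" in ev else ev
        pos_by, lab_by, idx_by = {}, {}, {}
        for chrom, grp in sub.groupby("chrom"):
            pos_by[chrom] = grp["pos"].to_numpy()
            idx_by[chrom] = grp.index.to_numpy()

        def stat(labels):
            return _co_co_stat(
                pos_by, {c: labels[idx_by[c]] for c in pos_by}
            )

        n_events = len(sub)
        event_index = sub.index.to_numpy()
    elif pair == "co_nco":
        if "kind" not in ev:
            raise ValueError("co_nco needs a 'kind' column")
        co = ev[ev["kind"] == "CO"]
        nco = ev[ev["kind"] == "NCO"]
        co_pos = {c: g["pos"].to_numpy() for c, g in co.groupby("chrom")}
        co_idx = {c: g.index.to_numpy() for c, g in co.groupby("chrom")}
        nco_pos = {c: g["pos"].to_numpy() for c, g in nco.groupby("chrom")}
        nco_idx = {c: g.index.to_numpy() for c, g in nco.groupby("chrom")}

        def stat(labels):
            return _co_nco_stat(
                co_pos, {c: labels[co_idx[c]] for c in co_pos},
                nco_pos, {c: labels[nco_idx[c]] for c in nco_pos},
            )

        n_events = len(ev)
        event_index = ev.index.to_numpy()
    else:
        raise ValueError("pair must be 'co_co' or 'co_nco'")

    base = np.asarray(tetrad_codes)
    observed = stat(base)
    if not np.isfinite(observed):
        raise ValueError("interference statistic undefined: no same-tetrad pairs")

    labels = base.copy()
    if exhaustive:
        n_assign = n_tetrads ** n_events
        if n_assign > 2_000_000:
            raise ValueError("exhaustive enumeration infeasible for this input")
        null = np.empty(n_assign)
        for i, combo in enumerate(itertools.product(range(n_tetrads), repeat=n_events)):
            labels[event_index] = combo
            null[i] = stat(labels)
        null = null[np.isfinite(null)]
        if direction == "greater":
            p = float((null >= observed).mean())
        else:
            p = float((null <= observed).mean())
        return PermutationResult(float(observed), null, p, direction, len(null))

    null = np.empty(n_iter)
    for i in range(n_iter):
        labels[event_index] = rng.integers(0, n_tetrads, size=n_events)
        null[i] = stat(labels)
    finite = null[np.isfinite(null)]
    p = _perm_p(finite, observed, direction)
    return PermutationResult(float(observed), null, p, direction, n_iter)


# ---------------------------------------------------------------------------
# sequence-derived values


def _flanked(sites: pd.DataFrame, flank: int, chrom_sizes: dict[str, int]) -> pd.DataFrame:
    out = sites.copy()
    out["start"] = np.maximum(out["start"] - flank, 0)
    out["end"] = out["end"] + flank
    if chrom_sizes:
        out["end"] = np.minimum(out["end"], out["chrom"].map(chrom_sizes).fillna(np.inf))
    out["end"] = out["end"].astype(int)
    return out


def _gc_cumsums(sequences: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C")) | (arr == ord("g")) | (arr == ord("c"))
        out[chrom] = np.concatenate([[0], np.cumsum(is_gc)])
    return out


def _interval_gc(intervals: pd.DataFrame, cums: dict[str, np.ndarray]) -> np.ndarray:
    vals = np.full(len(intervals), np.nan)
    for i, row in enumerate(intervals.itertuples()):
        cum = cums.get(row.chrom)
        if cum is None:
            continue
        s = max(0, int(row.start))
        e = min(len(cum) - 1, int(row.end))
        if e > s:
            vals[i] = (cum[e] - cum[s]) / (e - s)
    return vals


def gc_content_test(
    sites: pd.DataFrame,
    sequences: dict[str, str],
    mask: pd.DataFrame,
    flank: int = 500,
    n_background: int = 5_000,
    rng=None,
) -> dict:
    """GC content of flanked sites vs equally sized random mask regions.

    Welch's t test compares the means, a median-centred Levene test the
    variances.  Sites falling in unsequenced gaps are dropped (counted in
    the result).
    """
    rng = as_rng(rng)
    sizes = {c: len(s) for c, s in sequences.items()}
    fl = _flanked(sites, flank, sizes)
    cums = _gc_cumsums(sequences)
    vals = _interval_gc(fl, cums)
    dropped = int(np.isnan(vals).sum())
    vals = vals[~np.isnan(vals)]
    if len(vals) < 2:
        raise ValueError("need at least two sites with sequence for the variance test")
    lengths = (fl["end"] - fl["start"]).to_numpy()
    bg_len = rng.choice(lengths, size=n_background)
    chroms, starts, ends = sample_intervals(mask, bg_len, rng)
    bg = _interval_gc(pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}), cums)
    bg = bg[~np.isnan(bg)]
    t_stat, t_p = stats.ttest_ind(vals, bg, equal_var=False)
    l_stat, l_p = stats.levene(vals, bg, center="median")
    return {
        "site_values": vals,
        "background_values": bg,
        "mean_stat": float(t_stat),
        "mean_p": float(t_p),
        "var_stat": float(l_stat),
        "var_p": float(l_p),
        "direction": "lower" if vals.mean() < bg.mean() else "higher",
        "n_dropped": dropped,
    }


# ---------------------------------------------------------------------------
# quantitative tracks


def _track_arrays(track: pd.DataFrame):
    """Per-chromosome edge positions, cumulative signal and covered length."""
    out = {}
    for chrom, grp in track.groupby("chrom"):
        grp = grp.sort_values("start")
        edges = np.empty(2 * len(grp), dtype=np.int64)
        edges[0::2] = grp["start"].to_numpy()
        edges[1::2] = grp["end"].to_numpy()
        seg = np.diff(edges)  # alternating covered-bin / gap segments
        v = np.zeros(len(seg))
        v[0::2] = grp["value"].to_numpy()
        cov = np.zeros(len(seg))
        cov[0::2] = 1.0
        cum_sig = np.concatenate([[0.0], np.cumsum(v * seg)])
        cum_cov = np.concatenate([[0.0], np.cumsum(cov * seg)])
        out[chrom] = (edges, cum_sig, cum_cov)
    return out


def _interval_track_mean(intervals: pd.DataFrame, arrays) -> np.ndarray:
    def interp(edges, cum, x):
        return np.interp(x, edges, cum[: len(edges)])

    vals = np.full(len(intervals), np.nan)
    for i, row in enumerate(intervals.itertuples()):
        got = arrays.get(row.chrom)
        if got is None:
            continue
        edges, cum_sig, cum_cov = got
        s, e = int(row.start), int(row.end)
        sig = interp(edges, cum_sig, e) - interp(edges, cum_sig, s)
        cov = interp(edges, cum_cov, e) - interp(edges, cum_cov, s)
        if cov > 0:
            vals[i] = sig / cov
    return vals


def track_signal_test(
    sites: pd.DataFrame,
    track: pd.DataFrame,
    mask: pd.DataFrame,
    flank: int = 500,
    n_background: int = 5_000,
    rng=None,
    chrom_sizes: dict[str, int] | None = None,
) -> dict:
    """Mean track signal (methylation, MNase reads, ...) at sites vs mask
    background; Welch's t test with the direction of the difference."""
    rng = as_rng(rng)
    if track is None or len(track) == 0:
        raise ValueError("empty track")
    arrays = _track_arrays(track)
    fl = _flanked(sites, flank, chrom_sizes or {})
    vals = _interval_track_mean(fl, arrays)
    dropped = int(np.isnan(vals).sum())
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValueError("no site overlaps the track")
    lengths = (fl["end"] - fl["start"]).to_numpy()
    chroms, starts, ends = sample_intervals(mask, rng.choice(lengths, n_background), rng)
    bg = _interval_track_mean(
        pd.DataFrame({"chrom": chroms, "start": starts, "end": ends}), arrays
    )
    bg = bg[~np.isnan(bg)]
    if np.ptp(vals) == 0 and np.ptp(bg) == 0 and vals.mean() == bg.mean():
        t_stat, t_p = 0.0, 1.0  # constant track: no difference detectable
    else:
        t_stat, t_p = stats.ttest_ind(vals, bg, equal_var=False)
    return {
        "site_values": vals,
        "background_values": bg,
        "mean_stat": float(t_stat),
        "mean_p": float(t_p),
        "direction": "lower" if vals.mean() < bg.mean() else "higher",
        "n_dropped": dropped,
    }


# ---------------------------------------------------------------------------
# annotation enrichment

CATEGORIES = ("promoter", "gene_end", "gene_body", "transposon", "intergenic")


def _category_intervals(genome, promoter_bp: int, gene_end_bp: int):
    genes = genome.genes
    plus = genes["strand"] == "+"
    promoter = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.where(plus, genes["start"] - promoter_bp, genes["end"]),
            "end": np.where(plus, genes["start"], genes["end"] + promoter_bp),
        }
    )
    gene_end = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": np.where(plus, genes["end"] - gene_end_bp, genes["start"]),
            "end": np.where(plus, genes["end"], genes["start"] + gene_end_bp),
        }
    )
    return {
        "promoter": promoter,
        "gene_end": gene_end,
        "gene_body": genes[["chrom", "start", "end"]],
        "transposon": genome.transposons,
    }


def _classify(chroms, pos, cat_intervals):
    from tetrada.regions import positions_within

    out = np.full(len(pos), len(CATEGORIES) - 1, dtype=int)  # intergenic
    assigned = np.zeros(len(pos), dtype=bool)
    for ci, cat in enumerate(CATEGORIES[:-1]):
        iv = cat_intervals.get(cat)
        if iv is None or len(iv) == 0:
            continue
        hit = positions_within(chroms, pos, iv) & ~assigned
        out[hit] = ci
        assigned |= hit
    return out


def annotation_enrichment(
    sites: pd.DataFrame,
    genome,
    mask: pd.DataFrame,
    n_iter: int = 10_000,
    rng=None,
    promoter_bp: int = 500,
    gene_end_bp: int = 200,
) -> dict[str, PermutationResult]:
    """Site-midpoint enrichment per annotation category.

    Promoters are ``promoter_bp`` upstream of the TSS (strand-aware), gene
    ends the last ``gene_end_bp`` of a gene; precedence when categories
    overlap is promoter > gene end > gene body > transposon > intergenic.
    The null drops the same number of midpoints uniformly on the mask;
    p-values are two-sided.
    """
    rng = as_rng(rng)
    cats = _category_intervals(genome, promoter_bp, gene_end_bp)
    mid = ((sites["start"] + sites["end"]) // 2).to_numpy()
    obs = np.bincount(
        _classify(sites["chrom"].to_numpy(), mid, cats), minlength=len(CATEGORIES)
    )
    n = len(sites)
    bg_chrom, bg_pos = sample_positions(mask, n_iter * n, rng)
    bg_cat = _classify(bg_chrom, bg_pos, cats).reshape(n_iter, n)
    null_counts = np.stack(
        [(bg_cat == ci).sum(axis=1) for ci in range(len(CATEGORIES))], axis=1
    )
    out = {}
    for ci, cat in enumerate(CATEGORIES):
        null = null_counts[:, ci].astype(float)
        p = _perm_p(null, obs[ci], "two-sided")
        out[cat] = PermutationResult(float(obs[ci]), null, p, "two-sided", n_iter)
    return out


# ---------------------------------------------------------------------------
# motif rescreening (PWM scan with exact score p-values)

_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i
    _BASE_INDEX[ord(_b.lower())] = _i


def pwm_from_consensus(consensus: str, p_match: float = 0.91) -> np.ndarray:
    """Simple PWM: ``p_match`` on the consensus base, rest spread evenly."""
    pwm = np.full((len(consensus), 4), (1 - p_match) / 3)
    for i, b in enumerate(consensus.upper()):
        pwm[i, "ACGT".index(b)] = p_match
    return pwm


POLY_A_PWM = pwm_from_consensus("A" * 12, p_match=0.97)
GAA_PWM = pwm_from_consensus("GAA" * 3, p_match=0.91)


def pwm_score_threshold(
    pwm: np.ndarray, background=(0.25, 0.25, 0.25, 0.25), match_p: float = 0.001,
    precision: float = 1e-3,
):
    """Integerized log-odds scores and the minimal score whose exact tail
    probability under the background composition is < ``match_p``.

    The score distribution is enumerated by dynamic programming over the
    PWM columns on an integer grid of resolution ``precision``.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] == 0 or pwm.shape[1] != 4:
        raise ValueError("PWM must be a non-empty (k, 4) matrix")
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    scores = np.log2((pwm + 1e-9) / bg)
    q = np.round(scores / precision).astype(np.int64)
    if match_p >= 1.0:  # degenerate request: every window qualifies
        return q, int(q.min(axis=1).sum())
    # DP: start with the empty prefix at score 0
    cur = np.array([1.0])
    cur_lo = 0
    for row in q:
        new_lo = cur_lo + int(row.min())
        new_hi = cur_lo + len(cur) - 1 + int(row.max())
        new = np.zeros(new_hi - new_lo + 1)
        for j in range(4):
            off = cur_lo + int(row[j]) - new_lo
            new[off : off + len(cur)] += cur * bg[j]
        cur, cur_lo = new, new_lo
    tail = np.cumsum(cur[::-1])[::-1]
    above = np.flatnonzero(tail < match_p)
    if len(above) == 0:
        threshold = cur_lo + len(cur)  # unreachable: nothing matches
    else:
        threshold = cur_lo + int(above[0])
    return q, int(threshold)


def _scan_int_scores(codes: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Window sums of integer PWM scores over an encoded sequence."""
    k = len(q)
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        ok = c >= 0
        valid &= ok
        out += np.where(ok, q[j][np.clip(c, 0, 3)], 0)
    out[~valid] = np.iinfo(np.int64).min
    return out


def _has_match(seq: str, q: np.ndarray, q_rc: np.ndarray, threshold: int) -> bool:
    codes = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    s = _scan_int_scores(codes, q)
    if len(s) and s.max() >= threshold:
        return True
    s = _scan_int_scores(codes, q_rc)
    return bool(len(s) and s.max() >= threshold)


def motif_rescreen(
    pwm: np.ndarray,
    sites: pd.DataFrame,
    sequences: dict[str, str],
    mask: pd.DataFrame,
    n_random: int = 1_000,
    match_p: float = 0.001,
    flank: int = 500,
    rng=None,
    n_iter: int = 1_000,
    background_composition=(0.25, 0.25, 0.25, 0.25),
) -> PermutationResult:
    """Enrichment of PWM matches at recombination sites.

    A region matches when any window (either strand) reaches the score
    whose exact p-value under the background base composition is below
    ``match_p``.  The observed statistic is the number of flanked sites
    containing a match; the null resamples site-sized sets from a pool of
    ``n_random`` random mask regions of the same lengths.
    """
    rng = as_rng(rng)
    q, threshold = pwm_score_threshold(pwm, background_composition, match_p)
    q_rc = q[::-1, ::-1]
    sizes = {c: len(s) for c, s in sequences.items()}
    fl = _flanked(sites, flank, sizes)

    def region_match(chrom, s, e) -> bool:
        seq = sequences.get(chrom)
        if seq is None:
            return False
        return _has_match(seq[int(s) : int(e)], q, q_rc, threshold)

    obs = sum(region_match(r.chrom, r.start, r.end) for r in fl.itertuples())
    lengths = (fl["end"] - fl["start"]).to_numpy()
    bg_len = rng.choice(lengths, size=n_random)
    chroms, starts, ends = sample_intervals(mask, bg_len, rng)
    pool = np.array(
        [region_match(c, s, e) for c, s, e in zip(chroms, starts, ends)], dtype=bool
    )
    n_sites = len(fl)
    null = np.empty(n_iter)
    replace = n_sites > len(pool)
    for i in range(n_iter):
        null[i] = pool[rng.choice(len(pool), size=n_sites, replace=replace)].sum()
    p = _perm_p(null, obs, "greater")
    return PermutationResult(float(obs), null, p, "greater", n_iter)


# ---------------------------------------------------------------------------
# nucleosome-exclusion distances

POLY_A_RE = re.compile(r"A{10,}|T{10,}")
CG_TRIPLET_RE = re.compile(r"[CG]{3}[ACGT]{2}[CG]{3}[ACGT]{2}[CG]{3}")


def nucleosome_exclusion_sites(seq: str) -> np.ndarray:
    """Midpoints of (A)10+/(T)10+ runs and ([C/G]3 N2)x3 motifs."""
    mids = [
        (m.start() + m.end()) // 2
        for pat in (POLY_A_RE, CG_TRIPLET_RE)
        for m in pat.finditer(seq.upper())
    ]
    return np.sort(np.array(mids, dtype=np.int64))


def nucleosome_exclusion_distance(
    sites: pd.DataFrame,
    sequences: dict[str, str],
    mask: pd.DataFrame,
    n_background: int = 5_000,
    rng=None,
) -> dict:
    """Distance from site midpoints to the nearest nucleosome-exclusion
    motif, against random mask midpoints; one-sided rank test ("closer")."""
    rng = as_rng(rng)
    motif_pos = {c: nucleosome_exclusion_sites(s) for c, s in sequences.items()}

    def dists(chroms, pos):
        out = np.full(len(pos), np.inf)
        for i, (c, p) in enumerate(zip(chroms, pos)):
            mp = motif_pos.get(c)
            if mp is None or len(mp) == 0:
                continue
            j = np.searchsorted(mp, p)
            left = abs(p - mp[j - 1]) if j > 0 else np.inf
            right = abs(mp[j] - p) if j < len(mp) else np.inf
            out[i] = min(left, right)
        return out

    mid = ((sites["start"] + sites["end"]) // 2).to_numpy()
    site_d = dists(sites["chrom"].to_numpy(), mid)
    n_inf = int(np.isinf(site_d).sum())
    if n_inf:
        warnings.warn(f"{n_inf} sites on chromosomes without any motif; dropped")
    site_d = site_d[np.isfinite(site_d)]
    bg_chrom, bg_pos = sample_positions(mask, n_background, rng)
    bg_d = dists(bg_chrom, bg_pos)
    bg_d = bg_d[np.isfinite(bg_d)]
    if len(site_d) == 0 or len(bg_d) == 0:
        raise ValueError("no finite distances to compare")
    u_stat, p = stats.mannwhitneyu(site_d, bg_d, alternative="less")
    return {
        "site_distances": site_d,
        "background_distances": bg_d,
        "stat": float(u_stat),
        "p": float(p),
        "direction": "closer" if np.median(site_d) < np.median(bg_d) else "farther",
        "n_dropped": n_inf,
    }
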