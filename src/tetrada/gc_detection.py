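"""Gene-conversion detection, artifact filtering and rate estimation.

Non-crossover gene conversions (NCO-GCs) appear as confidently genotyped
markers whose genotype differs from the surrounding haplotype block:
type-1 events turn a homozygous genotype heterozygous (the expected allele
equals the recipient's), type-2 events turn a heterozygous genotype
homozygous.  Because the two marker classes are equally frequent, a type-1
excess is the fingerprint of alignment artifacts rather than biology, and a
cascade of marker filters (annotation proximity, parental heterozygosity,
three-haplotype read evidence, alignability) removes them.  CO-associated
conversions are the 3:1-segregating markers between the two reciprocal
transition points of a paired crossover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tetrada.genotyping import NOCALL
from tetrada.regions import positions_within


@dataclass
class FilterConfig:
    """Windows and thresholds of the marker-filter cascade."""

    quality_min: int = 24
    dup_te_pad: int = 2_000  # extension around duplications / transposons
    het_parent_pad: int = 1_000  # around parental-heterozygous positions
    init_pad: int = 150  # around any two-allele evidence in a parent
    het_parent_minor_frac: float = 0.15
    het_parent_min_cov: int = 10
    init_min_reads: int = 2
    three_parent_window: int = 300  # ~read-pair span
    three_parent_min_reads: int = 3
    alignability_floor: float = 0.5


@dataclass
class RateEstimate:
    numerator: int
    denominator: int
    rate: float
    sd: float

    def __post_init__(self):
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if self.numerator > self.denominator:
            raise ValueError("numerator exceeds denominator")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


PARENT_SAMPLES = ("P1", "P2", "CVI")


def classify_marker_type(markers: pd.DataFrame, expected_donor: np.ndarray) -> np.ndarray:
    """Type-1/2 classification given the background (expected) donor parent.

    Returns 1 where the expected allele equals the recipient's (conversion
    would look homozygous -> heterozygous), 2 where it differs, and 0 for
    recipient alleles matching neither parent (excluded, flagged upstream).
    """
    expected = np.asarray(expected_donor)
    recipient = markers["recipient_class"].to_numpy()
    out = np.where(recipient == expected, 1, 2).astype(np.int8)
    out[recipient > 1] = 0
    return out


def _parent_own_class(sample: str, recipient_class: np.ndarray) -> np.ndarray:
    if sample == "P1":
        return np.zeros(len(recipient_class), dtype=np.int8)
    if sample == "P2":
        return np.ones(len(recipient_class), dtype=np.int8)
    return recipient_class.astype(np.int8)


def apply_filters(
    markers: pd.DataFrame,
    counts: pd.DataFrame,
    genome,
    config: FilterConfig | None = None,
    alignability: pd.DataFrame | None = None,
    sanger_blacklist: pd.DataFrame | None = None,
):
    """Run the marker-filter cascade; returns ``(filters, provenance)``.

    ``filters`` holds one boolean pass column per named filter plus the
    conjunction ``final``; ``provenance`` lists filters skipped for missing
    inputs.  Counts must include the parental samples P1/P2/CVI for the
    parental-heterozygosity and three-parent filters.
    """
    cfg = config or FilterConfig()
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    n = len(markers)
    provenance: list[str] = []
    out = pd.DataFrame({"chrom": chroms, "pos": pos})

    out["quality"] = markers["quality"].to_numpy() >= cfg.quality_min

    dup_te = pd.concat(
        [genome.duplications, genome.transposons], ignore_index=True
    ) if genome is not None else None
    if dup_te is not None and len(dup_te):
        out["dup_te_2kb"] = ~positions_within(chroms, pos, dup_te, pad=cfg.dup_te_pad)
    else:
        out["dup_te_2kb"] = True
        provenance.append("dup_te_2kb skipped: no duplication/transposon annotation")

    parents = counts[counts["sample"].isin(PARENT_SAMPLES)]
    if len(parents):
        het_pos, weak_pos = [], []
        mk = markers[["chrom", "pos", "recipient_class"]]
        for sample, grp in parents.groupby("sample"):
            grp = grp.merge(mk, on=["chrom", "pos"], how="left")
            own_cls = _parent_own_class(sample, grp["recipient_class"].to_numpy())
            mat = grp[["n_P1", "n_P2", "n_other"]].to_numpy()
            own = mat[np.arange(len(grp)), np.clip(own_cls, 0, 2)]
            depth = mat.sum(axis=1)
            minor = depth - own
            with np.errstate(invalid="ignore", divide="ignore"):
                frac = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
            het = (depth >= cfg.het_parent_min_cov) & (frac >= cfg.het_parent_minor_frac)
            weak = minor >= cfg.init_min_reads
            het_pos.append(grp.loc[het, ["chrom", "pos"]])
            weak_pos.append(grp.loc[weak, ["chrom", "pos"]])
        het_df = pd.concat(het_pos, ignore_index=True)
        weak_df = pd.concat(weak_pos, ignore_index=True)
        out["het_parent_1kb"] = ~positions_within(
            chroms, pos, _points_to_intervals(het_df), pad=cfg.het_parent_pad
        )
        out["init_150bp"] = ~positions_within(
            chroms, pos, _points_to_intervals(weak_df), pad=cfg.init_pad
        )
    else:
        out["het_parent_1kb"] = True
        out["init_150bp"] = True
        provenance.append("het_parent_1kb/init_150bp skipped: no parental counts")

    # three-haplotype evidence: at a recipient-informative site a sample can
    # legitimately show the recipient-specific allele plus ONE parental
    # allele; all three at once means three haplotypes align to the locus
    tri = markers["triallelic"].to_numpy()
    tri_loci = markers.loc[tri, ["chrom", "pos"]]
    if len(tri_loci):
        k = cfg.three_parent_min_reads
        ev = counts.merge(tri_loci, on=["chrom", "pos"], how="inner")
        bad = ev[(ev["n_P1"] >= k) & (ev["n_P2"] >= k) & (ev["n_other"] >= k)]
        bad_loci = bad[["chrom", "pos"]].drop_duplicates()
        out["three_parent_reads"] = ~positions_within(
            chroms, pos, _points_to_intervals(bad_loci), pad=cfg.three_parent_window
        )
    else:
        out["three_parent_reads"] = True
        provenance.append("three_parent_reads skipped: no recipient-informative sites")

    if alignability is not None and len(alignability):
        inside_low = positions_within(
            chroms, pos, alignability[alignability["value"] < cfg.alignability_floor]
        )
        out["low_alignability"] = ~inside_low
    else:
        out["low_alignability"] = True
        provenance.append("low_alignability skipped: no alignability track")

    if sanger_blacklist is not None and len(sanger_blacklist):
        out["sanger_2to2"] = ~positions_within(
            chroms, pos, _points_to_intervals(sanger_blacklist)
        )
    else:
        out["sanger_2to2"] = True
        provenance.append("sanger_2to2 skipped: no blacklist supplied")

    filter_cols = [
        "quality", "dup_te_2kb", "het_parent_1kb", "init_150bp",
        "three_parent_reads", "low_alignability", "sanger_2to2",
    ]
    out["final"] = out[filter_cols].all(axis=1)
    return out, provenance


def _points_to_intervals(df: pd.DataFrame) -> pd.DataFrame:
    if len(df) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "start": df["pos"].to_numpy(),
         "end": df["pos"].to_numpy() + 1}
    )


# ---------------------------------------------------------------------------
# background assignment


def assign_background(calls: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Attach the haplotype-block state each call sits in (-1 if none)."""
    calls = calls.copy()
    calls["background"] = np.int8(-1)
    for (sample, chrom), grp in blocks.groupby(["sample", "chrom"], sort=False):
        sel = (calls["sample"] == sample) & (calls["chrom"] == chrom)
        if not sel.any():
            continue
        pos = calls.loc[sel, "pos"].to_numpy()
        starts = grp["start_pos"].to_numpy()
        ends = grp["end_pos"].to_numpy()
        states = grp["state"].to_numpy()
        order = np.argsort(starts)
        starts, ends, states = starts[order], ends[order], states[order]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        ok[ok] &= pos[ok] <= ends[idx[ok]]
        bg = np.full(len(pos), -1, dtype=np.int8)
        bg[ok] = states[idx[ok]]
        calls.loc[sel, "background"] = bg
    return calls


# ---------------------------------------------------------------------------
# NCO-GC detection


def detect_nco_gc(
    calls: pd.DataFrame,
    blocks: pd.DataFrame,
    filters: pd.DataFrame | None = None,
    tetrads: dict[str, str] | None = None,
    min_cov: int = 50,
    exclude_regions: pd.DataFrame | None = None,
    markers: pd.DataFrame | None = None,
    reciprocal_flag_window: int = 10_000,
):
    """Detect NCO gene-conversion tracts; returns ``(events, flagged)``.

    Confidently genotyped markers (donor assigned, depth >= ``min_cov``,
    passing ``filters``, outside crossover-associated ``exclude_regions``)
    that disagree with their haplotype block are conversion candidates;
    candidates adjacent in the confident-marker sequence with no intervening
    concordant call merge into one tract.  For complete tetrads a marker
    discordant in two or more products violates 3:1 segregation and is
    flagged as an artifact instead of emitted.  Candidate tracts of one
    tetrad lying within ``reciprocal_flag_window`` of each other in two
    products with opposite directions are the footprint of a close double
    crossover absorbed by block merging (conversion is non-reciprocal), so
    both are flagged rather than emitted.
    """
    tetrads = tetrads or {}
    conf = calls[(calls["donor"] != NOCALL) & (calls["depth"] >= min_cov)].copy()
    if markers is not None and "recipient_class" not in conf:
        conf = conf.merge(
            markers[["chrom", "pos", "recipient_class"]], on=["chrom", "pos"], how="left"
        )
    if filters is not None:
        passing = filters[filters["final"]][["chrom", "pos"]]
        conf = conf.merge(passing, on=["chrom", "pos"], how="inner")
    if exclude_regions is not None and len(exclude_regions):
        inside = positions_within(
            conf["chrom"].to_numpy(), conf["pos"].to_numpy(), exclude_regions
        )
        conf = conf[~inside]
    conf = assign_background(conf, blocks)
    conf = conf[conf["background"] >= 0]
    conf["discordant"] = conf["donor"] != conf["background"]

    # tetrad 3:1 verification
    flagged_rows = []
    if tetrads:
        sub = conf[conf["sample"].isin(tetrads)]
        disc = sub[sub["discordant"]]
        if len(disc):
            disc = disc.copy()
            disc["meiosis"] = disc["sample"].map(tetrads)
            n_disc = disc.groupby(["meiosis", "chrom", "pos"]).size()
            bad = n_disc[n_disc >= 2].reset_index()[["meiosis", "chrom", "pos"]]
            if len(bad):
                key = conf["sample"].map(tetrads).fillna("")
                bad_keys = set(map(tuple, bad.to_numpy()))
                is_bad = [
                    (k, c, p) in bad_keys
                    for k, c, p in zip(key, conf["chrom"], conf["pos"])
                ]
                is_bad = np.asarray(is_bad)
                flagged_rows.append(conf[is_bad & conf["discordant"].to_numpy()])
                conf = conf[~is_bad]
    flagged = (
        pd.concat(flagged_rows, ignore_index=True)
        if flagged_rows
        else conf.iloc[0:0].copy()
    )

    events = []
    for (sample, chrom), grp in conf.groupby(["sample", "chrom"], sort=True):
        grp = grp.sort_values("pos")
        disc = grp["discordant"].to_numpy()
        if not disc.any():
            continue
        pos = grp["pos"].to_numpy()
        donor = grp["donor"].to_numpy()
        background = grp["background"].to_numpy()
        recipient = (
            grp["recipient_class"].to_numpy()
            if "recipient_class" in grp
            else None
        )
        change = np.flatnonzero(np.diff(disc.astype(int))) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [len(disc)]])
        for s, e in zip(starts, ends):
            if not disc[s]:
                continue
            to_parent = int(np.round(donor[s:e].mean()))
            # type per marker: 1 if recipient allele equals the background
            bg = background[s:e]
            if recipient is not None:
                n_t1 = int((recipient[s:e] == bg).sum())
                n_t2 = int((e - s) - n_t1)
            else:
                n_t1 = n_t2 = 0
            events.append(
                {
                    "kind": "NCO_GC",
                    "sample": sample,
                    "meiosis": tetrads.get(sample, sample),
                    "chrom": chrom,
                    "start": int(pos[s]),
                    "end": int(pos[e - 1]),
                    "n_markers": int(e - s),
                    "to_parent": to_parent,
                    "n_type1": n_t1,
                    "n_type2": n_t2,
                }
            )
    events = pd.DataFrame(
        events,
        columns=["kind", "sample", "meiosis", "chrom", "start", "end",
                 "n_markers", "to_parent", "n_type1", "n_type2"],
    )
    # reciprocal-pattern check: nearby opposite-direction candidate tracts in
    # two products of one tetrad are a crossover signature, not conversions
    if tetrads and len(events):
        drop = set()
        tet_ev = events[events["sample"].isin(tetrads)]
        for (_, _), grp in tet_ev.groupby(["meiosis", "chrom"], sort=False):
            recs = list(grp.itertuples())
            for i in range(len(recs)):
                for j in range(i + 1, len(recs)):
                    a, b = recs[i], recs[j]
                    if a.sample == b.sample or a.to_parent == b.to_parent:
                        continue
                    gap = max(a.start, b.start) - min(a.end, b.end)
                    if gap <= reciprocal_flag_window:
                        drop.update((a.Index, b.Index))
        if drop:
            reciprocal = events.loc[sorted(drop)].copy()
            reciprocal["flag"] = "reciprocal_pattern"
            flagged = pd.concat([flagged, reciprocal], ignore_index=True)
            events = events.drop(index=sorted(drop)).reset_index(drop=True)
    return events, flagged


def count_confident(calls: pd.DataFrame, blocks, filters=None, min_cov: int = 50,
                    exclude_regions=None) -> int:
    """Denominator for conversion rates: confidently genotyped marker-loci."""
    conf = calls[(calls["donor"] != NOCALL) & (calls["depth"] >= min_cov)]
    if filters is not None:
        passing = filters[filters["final"]][["chrom", "pos"]]
        conf = conf.merge(passing, on=["chrom", "pos"], how="inner")
    if exclude_regions is not None and len(exclude_regions):
        inside = positions_within(
            conf["chrom"].to_numpy(), conf["pos"].to_numpy(), exclude_regions
        )
        conf = conf[~inside]
    conf = assign_background(conf, blocks)
    return int((conf["background"] >= 0).sum())


def nco_frequency_curve(
    calls, blocks, cov_grid, filters=None, tetrads=None, exclude_regions=None
) -> np.ndarray:
    """Apparent conversion frequency at each minimum-coverage threshold."""
    freqs = []
    for c in cov_grid:
        ev, _ = detect_nco_gc(
            calls, blocks, filters=filters, tetrads=tetrads, min_cov=int(c),
            exclude_regions=exclude_regions,
        )
        denom = count_confident(
            calls, blocks, filters=filters, min_cov=int(c),
            exclude_regions=exclude_regions,
        )
        freqs.append(ev["n_markers"].sum() / denom if denom else np.nan)
    return np.asarray(freqs)


# ---------------------------------------------------------------------------
# CO-associated conversions


def detect_co_gc(
    co_events: pd.DataFrame,
    calls: pd.DataFrame,
    tetrads: dict[str, str],
    min_cov: int = 50,
) -> pd.DataFrame:
    """3:1-segregating markers at paired crossover breakpoints.

    For each cleanly paired CO the markers spanned by the two products'
    transition intervals are checked across all four tetrad products; those
    with exactly one discordant product form the CO conversion tract.  All
    markers of a tract must convert the same way (co-conversion); tracts
    with both directions are flagged complex.  Events where fewer than four
    products are callable over the span are marked insufficient.
    """
    by_meiosis: dict[str, list[str]] = {}
    for sample, meiosis in tetrads.items():
        by_meiosis.setdefault(meiosis, []).append(sample)

    conf = calls[(calls["donor"] != NOCALL) & (calls["depth"] >= min_cov)]
    rows = []
    for idx, ev in co_events.iterrows():
        if ev["flag"] != "" or len(ev["products"]) != 2:
            continue
        samples = by_meiosis.get(ev["meiosis"], [])
        span = conf[
            (conf["chrom"] == ev["chrom"])
            & (conf["pos"] >= ev["left_pos"])
            & (conf["pos"] <= ev["right_pos"])
            & conf["sample"].isin(samples)
        ]
        if not len(span):
            continue
        pivot = span.pivot_table(index="pos", columns="sample", values="donor",
                                 aggfunc="first")
        complete = pivot.dropna()
        if complete.shape[1] < 4 or not len(complete):
            rows.append(
                {
                    "kind": "CO_GC", "co_index": idx, "meiosis": ev["meiosis"],
                    "chrom": ev["chrom"], "start": np.nan, "end": np.nan,
                    "n_markers": 0, "to_parent": -1, "flag": "insufficient_data",
                }
            )
            continue
        donors = complete.to_numpy()
        n_p1 = (donors == 0).sum(axis=1)
        three_one = (n_p1 == 3) | (n_p1 == 1)
        if not three_one.any():
            continue
        pos31 = complete.index.to_numpy()[three_one]
        majority = np.where(n_p1[three_one] == 3, 0, 1)
        flag = "" if len(set(majority)) == 1 else "complex"
        rows.append(
            {
                "kind": "CO_GC", "co_index": idx, "meiosis": ev["meiosis"],
                "chrom": ev["chrom"], "start": int(pos31.min()),
                "end": int(pos31.max()), "n_markers": int(three_one.sum()),
                "to_parent": int(majority[0]), "flag": flag,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["kind", "co_index", "meiosis", "chrom", "start", "end",
                 "n_markers", "to_parent", "flag"],
    )


# ---------------------------------------------------------------------------
# rates and DH mutations


def estimate_rate(
    n_converted: int, n_assayed: int, per_meiosis: list[tuple[int, int]] | None = None
) -> RateEstimate:
    """Conversion (or mutation) rate per assayed site.

    With ``per_meiosis`` pairs (numerator_i, denominator_i) the sd comes
    from a leave-one-meiosis-out jackknife; otherwise it is the binomial
    standard error.
    """
    if n_assayed <= 0:
        raise ValueError("n_assayed must be positive")
    if n_converted > n_assayed:
        raise ValueError("more conversions than assayed loci")
    rate = n_converted / n_assayed
    if per_meiosis:
        m = len(per_meiosis)
        tot_n = sum(x for x, _ in per_meiosis)
        tot_d = sum(d for _, d in per_meiosis)
        loo = np.array(
            [(tot_n - x) / (tot_d - d) for x, d in per_meiosis if tot_d - d > 0]
        )
        sd = float(np.sqrt((m - 1) / m * ((loo - loo.mean()) ** 2).sum())) if len(loo) > 1 else 0.0
    else:
        sd = float(np.sqrt(rate * (1 - rate) / n_assayed))
    return RateEstimate(int(n_converted), int(n_assayed), rate, sd)


def detect_dh_mutations(
    site_counts: pd.DataFrame,
    cutoff,
    min_score: int = 32,
    min_cov: int = 10,
) -> pd.DataFrame:
    """Spontaneous mutations private to one doubled-haploid line.

    A site is a mutation when exactly one sample shows a confident
    homozygous non-parental allele (depth >= ``min_cov``, score >=
    ``min_score``, allele frequency >= the cutoff) and every other sample
    confidently shows the parental allele.  Variants shared by two or more
    samples are inherited, not spontaneous, and are excluded.
    """
    df = site_counts.copy()
    depth = (df["n_parental"] + df["n_alt"]).to_numpy()
    c = cutoff.cutoff_for(depth)
    callable_ = (depth >= min_cov) & (df["score"].to_numpy() >= min_score)
    with np.errstate(invalid="ignore", divide="ignore"):
        af_alt = np.where(depth > 0, df["n_alt"].to_numpy() / np.maximum(depth, 1), 0.0)
    df["is_alt"] = callable_ & (af_alt >= c)
    df["is_parental"] = callable_ & ((1 - af_alt) >= c)

    g = df.groupby("pos")
    n_samples = df["sample"].nunique()
    agg = g.agg(
        n_alt_samples=("is_alt", "sum"),
        n_parental_samples=("is_parental", "sum"),
    )
    hits = agg[(agg["n_alt_samples"] == 1) & (agg["n_parental_samples"] == n_samples - 1)]
    out = df[df["is_alt"] & df["pos"].isin(hits.index)][["sample", "pos"]]
    return out.reset_index(drop=True)
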