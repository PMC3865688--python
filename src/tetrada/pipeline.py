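"""End-to-end drivers tying genotyping, filtering and conversion detection.

These wrappers run the standard analysis order on a tetrad (or DH) cohort:

1. lenient genotype calls -> block merging -> crossover events,
2. stringent calls at the conversion-detection coverage threshold,
3. marker-filter cascade,
4. CO-associated conversions at paired breakpoints,
5. NCO conversions outside crossover regions, plus the confident-locus
   denominator for rate estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tetrada import gc_detection as gcd
from tetrada import genotyping as gt
from tetrada.af_model import CutoffModel


@dataclass
class TetradAnalysis:
    tetrads: dict[str, str]
    cutoff: CutoffModel
    blocks: pd.DataFrame
    candidates: pd.DataFrame
    seedless: pd.DataFrame
    co_events: pd.DataFrame
    calls: pd.DataFrame  # at the detection coverage threshold
    co_gc: pd.DataFrame
    nco_events: pd.DataFrame
    flagged_markers: pd.DataFrame
    filters: pd.DataFrame | None
    filter_provenance: list[str] = field(default_factory=list)
    n_confident: int = 0


def tetrad_sample_map(truth) -> dict[str, str]:
    return {f"{m.name}_{c + 1}": m.name for m in truth.meioses for c in range(4)}


def fit_cutoff_from_calls(
    calls_with_background: pd.DataFrame, markers: pd.DataFrame, **fit_kwargs
) -> CutoffModel:
    """Fit the beta/equal-error cutoff model from observed frequencies.

    Observations are the expected-donor allele frequencies at markers with
    an assigned background: type-1 markers (recipient allele equal to the
    expected donor's) behave homozygous, type-2 markers heterozygous.
    """
    df = calls_with_background
    df = df[df["background"] >= 0].merge(
        markers[["chrom", "pos", "recipient_class", "triallelic"]],
        on=["chrom", "pos"],
    )
    df = df[~df["triallelic"] & (df["depth"] > 0)]
    af_expected = np.where(df["background"] == 0, df["af_P1"], 1 - df["af_P1"])
    is_type1 = (df["recipient_class"] == df["background"]).to_numpy()
    return CutoffModel.fit(
        af_expected[is_type1],
        df["depth"].to_numpy()[is_type1],
        af_expected[~is_type1],
        df["depth"].to_numpy()[~is_type1],
        **fit_kwargs,
    )


def analyze_tetrads(
    markers: pd.DataFrame,
    counts: pd.DataFrame,
    genome,
    tetrads: dict[str, str],
    cutoff: CutoffModel | str = "fixed",
    fixed_cutoff: float = 0.889,
    min_cov_blocks: int = 3,
    min_cov_detect: int = 50,
    seed_min_markers: int = 25,
    use_filters: bool = True,
    filter_config=None,
) -> TetradAnalysis:
    """Run the tetrad pipeline; see the module docstring for the stages.

    ``cutoff`` may be a fitted :class:`CutoffModel`, the string ``"fixed"``
    (use ``fixed_cutoff``) or ``"fit"`` (fit the beta model from this
    cohort's own allele frequencies).
    """
    tcounts = counts[counts["sample"].isin(tetrads)]
    boot = CutoffModel.fixed(fixed_cutoff)
    calls_blocks = gt.call_genotypes(tcounts, markers, boot, min_cov=min_cov_blocks)
    blocks, candidates, seedless = gt.merge_blocks(calls_blocks, seed_min_markers)
    co_events = gt.detect_crossovers(blocks, tetrads)

    if cutoff == "fit":
        bg = gcd.assign_background(
            calls_blocks[calls_blocks["depth"] >= min_cov_detect], blocks
        )
        cutoff = fit_cutoff_from_calls(bg, markers)
    elif cutoff == "fixed":
        cutoff = boot
    calls = gt.call_genotypes(tcounts, markers, cutoff, min_cov=min_cov_detect)

    filters = provenance = None
    if use_filters:
        filters, provenance = gcd.apply_filters(
            markers, counts, genome, config=filter_config
        )

    co_gc = gcd.detect_co_gc(co_events, calls, tetrads, min_cov=min_cov_detect)
    clean = co_events[co_events["flag"] == ""]
    exclude = clean.rename(columns={"left_pos": "start", "right_pos": "end"})[
        ["chrom", "start", "end"]
    ]
    nco_events, flagged = gcd.detect_nco_gc(
        calls,
        blocks,
        filters=filters,
        tetrads=tetrads,
        min_cov=min_cov_detect,
        exclude_regions=exclude,
        markers=markers,
    )
    n_conf = gcd.count_confident(
        calls, blocks, filters=filters, min_cov=min_cov_detect, exclude_regions=exclude
    )
    return TetradAnalysis(
        tetrads=tetrads,
        cutoff=cutoff,
        blocks=blocks,
        candidates=candidates,
        seedless=seedless,
        co_events=co_events,
        calls=calls,
        co_gc=co_gc,
        nco_events=nco_events,
        flagged_markers=flagged,
        filters=filters,
        filter_provenance=provenance or [],
        n_confident=n_conf,
    )


def analyze_dh(
    markers: pd.DataFrame,
    counts: pd.DataFrame,
    genome,
    dh_samples: list[str],
    cutoff: CutoffModel | None = None,
    fixed_cutoff: float = 0.889,
    min_cov_blocks: int = 3,
    min_cov_detect: int = 10,
    seed_min_markers: int = 25,
    use_filters: bool = True,
    filter_config=None,
) -> TetradAnalysis:
    """DH-line pipeline: homozygous genotyping, CO calls and NCO detection.

    DH lines are fully homozygous, so a lower detection coverage suffices
    (default 10 vs 50 for the heterozygous tetrad offspring).
    """
    dcounts = counts[counts["sample"].isin(dh_samples)]
    cutoff = cutoff or CutoffModel.fixed(fixed_cutoff)
    calls_blocks = gt.call_genotypes(
        dcounts, markers, cutoff, min_cov=min_cov_blocks, kind="dh"
    )
    blocks, candidates, seedless = gt.merge_blocks(calls_blocks, seed_min_markers)
    co_events = gt.detect_crossovers(blocks)
    calls = gt.call_genotypes(dcounts, markers, cutoff, min_cov=min_cov_detect, kind="dh")
    filters = provenance = None
    if use_filters:
        filters, provenance = gcd.apply_filters(
            markers, counts, genome, config=filter_config
        )
    clean = co_events[co_events["flag"] == ""]
    exclude = clean.rename(columns={"left_pos": "start", "right_pos": "end"})[
        ["chrom", "start", "end"]
    ]
    nco_events, flagged = gcd.detect_nco_gc(
        calls, blocks, filters=filters, min_cov=min_cov_detect,
        exclude_regions=exclude, markers=markers,
    )
    n_conf = gcd.count_confident(
        calls, blocks, filters=filters, min_cov=min_cov_detect, exclude_regions=exclude
    )
    return TetradAnalysis(
        tetrads={},
        cutoff=cutoff,
        blocks=blocks,
        candidates=candidates,
        seedless=seedless,
        co_events=co_events,
        calls=calls,
        co_gc=pd.DataFrame(),
        nco_events=nco_events,
        flagged_markers=flagged,
        filters=filters,
        filter_provenance=provenance or [],
        n_confident=n_conf,
    )


# ---------------------------------------------------------------------------
# truth comparison helpers (used by tests and the acceptance checks)


def co_recovery(truth, co_events: pd.DataFrame) -> dict:
    """Fraction of true crossovers whose position falls inside a clean
    event's breakpoint interval of the right meiosis."""
    clean = co_events[co_events["flag"] == ""]
    total = hit = 0
    for m in truth.meioses:
        evm = clean[clean["meiosis"] == m.name]
        for co in m.cos:
            total += 1
            inside = evm[
                (evm["chrom"] == co.chrom)
                & (evm["left_pos"] <= co.pos)
                & (evm["right_pos"] >= co.pos)
            ]
            hit += len(inside) > 0
    return {"n_true": total, "n_recovered": hit,
            "recovery": hit / total if total else np.nan}


def nco_recovery(truth, analysis: TetradAnalysis, markers: pd.DataFrame) -> dict:
    """Recovery of true NCO tracts that are detectable at all.

    Detectable = the tract overlaps at least one marker that is confidently
    genotyped (and filter-passing) in the converted product.  Also counts
    emitted events not matching any true tract (false positives).
    """
    from tetrada.regions import positions_within

    calls = analysis.calls
    conf = calls[(calls["donor"] >= 0)]
    if analysis.filters is not None:
        conf = conf.merge(
            analysis.filters[analysis.filters["final"]][["chrom", "pos"]],
            on=["chrom", "pos"],
        )
    clean_co = analysis.co_events[analysis.co_events["flag"] == ""]
    if len(clean_co):
        exclude = clean_co.rename(
            columns={"left_pos": "start", "right_pos": "end"}
        )[["chrom", "start", "end"]]
        inside = positions_within(
            conf["chrom"].to_numpy(), conf["pos"].to_numpy(), exclude
        )
        conf = conf[~inside]
    ev = analysis.nco_events
    detectable = recovered = 0
    matched = set()
    sample_of = {}
    for m in truth.meioses:
        for c in range(4):
            sample_of[(m.name, c)] = f"{m.name}_{c + 1}"
    for m in truth.meioses:
        for t in m.tracts:
            if t.kind != "NCO_GC":
                continue
            sample = sample_of[(m.name, t.chromatid)]
            inside = conf[
                (conf["sample"] == sample)
                & (conf["chrom"] == t.chrom)
                & (conf["pos"] >= t.start)
                & (conf["pos"] < t.end)
            ]
            if not len(inside):
                continue
            detectable += 1
            hits = ev[
                (ev["sample"] == sample)
                & (ev["chrom"] == t.chrom)
                & (ev["start"] <= t.end)
                & (ev["end"] >= t.start - 1)
            ]
            if len(hits):
                recovered += 1
                matched.update(hits.index)
    false_pos = int(len(ev) - len(matched & set(ev.index))) if len(ev) else 0
    return {
        "n_detectable": detectable,
        "n_recovered": recovered,
        "n_events": int(len(ev)),
        "n_false": false_pos,
    }
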