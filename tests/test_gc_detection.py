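"""Conversion detection, the filter cascade, rates and DH mutations."""

import numpy as np
import pandas as pd
import pytest

from tetrada.af_model import CutoffModel
from tetrada.gc_detection import (
    FilterConfig,
    apply_filters,
    classify_marker_type,
    detect_dh_mutations,
    estimate_rate,
)
from tetrada.pipeline import (
    analyze_dh,
    analyze_tetrads,
    nco_recovery,
    tetrad_sample_map,
)
from tetrada.synthetic_data import simulate_dh_mutation_counts


def test_classify_marker_type():
    markers = pd.DataFrame(
        {
            "chrom": "c1",
            "pos": [0, 1, 2],
            "recipient_class": np.array([0, 0, 2], dtype=np.int8),
        }
    )
    expected = np.array([0, 1, 0])  # expected donor parent per marker
    t = classify_marker_type(markers, expected)
    assert t.tolist() == [1, 2, 0]  # match->type1, differ->type2, tri-allelic->excluded


def _genome_with_dup(dup_start=10_000, dup_end=12_000):
    from tetrada.synthetic_data import GenomeModel

    return GenomeModel(
        chromosomes=[("c1", 100_000)],
        pericentromere={"c1": (45_000, 55_000)},
        genes=pd.DataFrame(columns=["chrom", "start", "end", "strand"]),
        transposons=pd.DataFrame(columns=["chrom", "start", "end"]),
        duplications=pd.DataFrame(
            [("c1", dup_start, dup_end)], columns=["chrom", "start", "end"]
        ),
    )


def test_duplication_window_boundary():
    """2 kb window: 1,500 bp from the edge fails, 2,001 bp passes."""
    markers = pd.DataFrame(
        {
            "chrom": "c1",
            "pos": [12_000 + 1_500, 12_000 + 2_001],
            "allele_P1": "A",
            "allele_P2": "G",
            "recipient_class": np.int8(0),
            "quality": 40,
            "triallelic": False,
            "decoy": np.int8(-1),
        }
    )
    empty_counts = pd.DataFrame(
        columns=["sample", "chrom", "pos", "n_P1", "n_P2", "n_other", "depth"]
    )
    filters, prov = apply_filters(markers, empty_counts, _genome_with_dup())
    assert filters["dup_te_2kb"].tolist() == [False, True]
    assert any("parental" in p for p in prov)


def test_filter_cascade_removes_artifact_conversions(artifact_cohort):
    """Unfiltered analysis shows a type-1-biased excess of false
    conversions at artifact loci; the cascade removes all of them."""
    _, genome, markers, truth, counts = artifact_cohort
    tetrads = tetrad_sample_map(truth)
    off = analyze_tetrads(markers, counts, genome, tetrads, use_filters=False)
    on = analyze_tetrads(markers, counts, genome, tetrads, use_filters=True)
    r_off = nco_recovery(truth, off, markers)
    r_on = nco_recovery(truth, on, markers)
    assert r_off["n_false"] > 0
    assert off.nco_events["n_type1"].sum() > 2 * off.nco_events["n_type2"].sum()
    assert r_on["n_false"] == 0
    assert r_on["n_recovered"] == r_on["n_detectable"]


def test_type_balance_after_filtering(study_cohort, artifact_cohort):
    """With artifacts filtered, type-1 and type-2 counts are binomially
    consistent with 1:1 (pooling both study fixtures for power)."""
    from scipy import stats

    t1 = t2 = 0
    for cohort in (study_cohort, artifact_cohort):
        _, genome, markers, truth, counts = cohort
        res = analyze_tetrads(markers, counts, genome, tetrad_sample_map(truth))
        t1 += int(res.nco_events["n_type1"].sum())
        t2 += int(res.nco_events["n_type2"].sum())
    n = t1 + t2
    assert n > 0
    lo, hi = stats.binom.interval(0.99, n, 0.5)
    assert lo <= t1 <= hi


def test_clean_fixture_recovery_and_tracts(small_cohort):
    _, genome, markers, truth, counts = small_cohort
    tetrads = tetrad_sample_map(truth)
    res = analyze_tetrads(markers, counts, genome, tetrads)
    r = nco_recovery(truth, res, markers)
    assert r["n_false"] == 0
    assert r["n_recovered"] == r["n_detectable"]
    # NCO markers contiguous in the tract
    if len(res.nco_events):
        assert (res.nco_events["start"] <= res.nco_events["end"]).all()


def test_dh_pipeline_detects_multi_marker_tract(small_cohort):
    _, genome, markers, truth, counts = small_cohort
    dh = [d.sample for d in truth.dh]
    res = analyze_dh(markers, counts, genome, dh, min_cov_detect=10)
    # every emitted DH event corresponds to a true tract on the kept gamete
    for ev in res.nco_events.itertuples():
        d = next(x for x in truth.dh if x.sample == ev.sample)
        hit = [
            t
            for t in d.meiosis.tracts
            if t.chromatid == d.gamete
            and t.chrom == ev.chrom
            and t.start - 1 <= ev.end
            and t.end >= ev.start
        ]
        assert hit, f"no truth tract behind {ev}"


def test_rate_arithmetic_and_errors():
    assert f"{estimate_rate(10, 3_672_610).rate:.2g}" == "2.7e-06"
    assert f"{estimate_rate(7 + 10, 1_092_055 + 3_672_610).rate:.2g}" == "3.6e-06"
    r0 = estimate_rate(0, 1000)
    assert r0.rate == 0 and r0.sd == 0
    with pytest.raises(ValueError):
        estimate_rate(5, 0)
    with pytest.raises(ValueError):
        estimate_rate(10, 5)


def test_rate_jackknife_between_meiosis_sd():
    per = [(1, 100_000)] * 5 + [(0, 100_000)] * 5
    r = estimate_rate(5, 1_000_000, per_meiosis=per)
    assert r.rate == 5e-6 and r.sd > 0


def test_dh_mutation_calling(rng):
    samples = [f"DH{i}" for i in range(1, 11)]
    muts = [(5, "DH3"), (100, "DH7")]
    shared = [(300, "DH1"), (300, "DH2")]
    sc = simulate_dh_mutation_counts(400, samples, muts + shared, coverage=30, rng=rng)
    found = detect_dh_mutations(sc, CutoffModel.fixed(0.889))
    got = set(map(tuple, found[["sample", "pos"]].to_numpy()))
    assert got == {("DH3", 5), ("DH7", 100)}  # the shared variant is excluded


def test_dh_mutation_respects_thresholds(rng):
    samples = ["DH1", "DH2", "DH3"]
    sc = simulate_dh_mutation_counts(50, samples, [(7, "DH2")], coverage=30, rng=rng)
    sc.loc[(sc["pos"] == 7) & (sc["sample"] == "DH2"), "score"] = 10
    found = detect_dh_mutations(sc, CutoffModel.fixed(0.889), min_score=32)
    assert len(found) == 0


def test_rate_recovery_simulated():
    """A known per-site conversion rate is recovered within the sampling
    error over >= 1e6 assayed loci."""
    rng = np.random.default_rng(271828)
    n_assayed = 10_000_000
    true_rate = 5e-6
    hits = rng.binomial(n_assayed, true_rate)
    r = estimate_rate(hits, n_assayed)
    assert abs(r.rate - true_rate) <= 3 * np.sqrt(true_rate / n_assayed)
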