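"""Permutation and two-sample tests: exactness, calibration, planted signal."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from tetrada.context_stats import (
    GAA_PWM,
    POLY_A_PWM,
    annotation_enrichment,
    gc_content_test,
    interference_test,
    motif_rescreen,
    nucleosome_exclusion_distance,
    nucleosome_exclusion_sites,
    pwm_score_threshold,
    track_signal_test,
)
from tetrada.regions import sample_intervals
from tetrada.synthetic_data import (
    SimulationConfig,
    build_genome,
    plant_motif,
    simulate_cohort,
)


# ---------------------------------------------------------------------------
# interference


def test_interference_exhaustive_matches_brute_force():
    ev = pd.DataFrame(
        {
            "tetrad": ["A"] * 3 + ["B"] * 3,
            "chrom": "c1",
            "pos": [10, 50, 90, 30, 60, 95],
            "kind": "CO",
        }
    )
    res = interference_test(ev, exhaustive=True)
    pos = np.array([10, 30, 50, 60, 90, 95])
    lab0 = np.array([0, 1, 0, 1, 0, 1])  # labels in sorted-position order

    def stat(lab):
        ds = []
        for v in set(lab):
            ds.extend(np.diff(np.sort(pos[lab == v])))
        return np.mean(ds) if ds else np.nan

    obs = stat(lab0)
    null = [stat(np.array(c)) for c in itertools.product([0, 1], repeat=6)]
    null = [x for x in null if x == x]
    assert res.observed == pytest.approx(obs)
    assert res.p == pytest.approx(np.mean([x >= obs for x in null]))


def _co_events(shape, seed, n_tetrads=13):
    cfg = SimulationConfig(
        chromosomes=[(f"c{i}", 5_000_000) for i in range(1, 6)],
        n_tetrads=n_tetrads, n_dh=0, markers_per_bp=1e-5,
        interference_shape=shape, seed=seed, n_dsb=0, obligate_co=False,
    )
    _, _, truth = simulate_cohort(cfg)
    rows = [
        (m.name, co.chrom, co.pos, "CO") for m in truth.meioses for co in m.cos
    ]
    return pd.DataFrame(rows, columns=["tetrad", "chrom", "pos", "kind"])


def test_interference_type_one_calibration():
    """Without interference (shape 1) p-values are uniform."""
    ps = [
        interference_test(_co_events(1.0, 300 + s), n_iter=199,
                          rng=np.random.default_rng(s)).p
        for s in range(60)
    ]
    assert st.kstest(ps, "uniform").pvalue > 0.01


def test_interference_detects_strong_signal():
    hits = [
        interference_test(_co_events(10.0, 700 + s), n_iter=199,
                          rng=np.random.default_rng(s)).p < 0.05
        for s in range(25)
    ]
    assert np.mean(hits) >= 0.8


def test_interference_co_nco_pair_type():
    cfg = SimulationConfig(
        chromosomes=[("c1", 5_000_000)], n_tetrads=5, n_dh=0,
        markers_per_bp=1e-5, n_dsb=30, obligate_co=False, seed=17,
    )
    _, _, truth = simulate_cohort(cfg)
    rows = [(m.name, co.chrom, co.pos, "CO") for m in truth.meioses for co in m.cos]
    rows += [
        (m.name, t.chrom, (t.start + t.end) // 2, "NCO")
        for m in truth.meioses for t in m.tracts if t.kind == "NCO_GC"
    ]
    ev = pd.DataFrame(rows, columns=["tetrad", "chrom", "pos", "kind"])
    res = interference_test(ev, pair="co_nco", n_iter=199, rng=np.random.default_rng(0))
    assert 0 < res.p <= 1


def test_interference_needs_two_tetrads():
    ev = pd.DataFrame({"tetrad": ["A"] * 3, "chrom": "c1", "pos": [1, 2, 3],
                       "kind": "CO"})
    with pytest.raises(ValueError, match="two tetrads"):
        interference_test(ev)


# ---------------------------------------------------------------------------
# sequence / track / annotation statistics


@pytest.fixture(scope="module")
def seq_world():
    cfg = SimulationConfig(chromosomes=[("c1", 400_000), ("c2", 400_000)], seed=9)
    genome, markers, seqs = build_genome(cfg, with_sequence=True)
    return genome, seqs, genome.arm_mask()


def _random_sites(mask, n, length, rng):
    ch, s, e = sample_intervals(mask, np.full(n, length), rng)
    return pd.DataFrame({"chrom": ch, "start": s, "end": e})


def test_gc_content_calibration_and_planted(seq_world):
    genome, seqs, mask = seq_world
    ps = []
    for k in range(60):
        rng = np.random.default_rng(1000 + k)
        sites = _random_sites(mask, 25, 300, rng)
        r = gc_content_test(sites, seqs, mask, n_background=300, rng=rng)
        ps.append(r["mean_p"])
    assert st.kstest(ps, "uniform").pvalue > 0.001
    rng = np.random.default_rng(5)
    sites = _random_sites(mask, 25, 300, rng)
    seqs2 = dict(seqs)
    for row in sites.itertuples():
        plant_motif(seqs2, row.chrom, [max(0, row.start - 500)], "AT" * 700)
    r = gc_content_test(sites, seqs2, mask, n_background=300, rng=rng)
    assert r["mean_p"] <= 0.01 and r["direction"] == "lower"


def test_gc_content_single_site_rejected(seq_world):
    genome, seqs, mask = seq_world
    sites = _random_sites(mask, 1, 300, np.random.default_rng(0))
    with pytest.raises(ValueError, match="two sites"):
        gc_content_test(sites, seqs, mask, rng=np.random.default_rng(0))


def _depleted_track(chrom_sizes, sites, low=0.05, high=1.0, pad=500):
    segs = []
    for chrom, size in chrom_sizes:
        cur = 0
        sub = sites[sites["chrom"] == chrom].sort_values("start")
        for row in sub.itertuples():
            s, e = max(0, row.start - pad), min(size, row.end + pad)
            if s > cur:
                segs.append((chrom, cur, s, high))
            segs.append((chrom, s, e, low))
            cur = e
        if cur < size:
            segs.append((chrom, cur, size, high))
    return pd.DataFrame(segs, columns=["chrom", "start", "end", "value"])


def test_track_signal_constant_and_planted(seq_world):
    genome, seqs, mask = seq_world
    rng = np.random.default_rng(2)
    sites = _random_sites(mask, 25, 300, rng)
    const = pd.DataFrame(
        [(c, 0, s, 1.0) for c, s in genome.chromosomes],
        columns=["chrom", "start", "end", "value"],
    )
    r = track_signal_test(sites, const, mask, n_background=300, rng=rng)
    assert r["mean_p"] == pytest.approx(1.0)
    dep = _depleted_track(genome.chromosomes, sites)
    r2 = track_signal_test(sites, dep, mask, n_background=300, rng=rng)
    assert r2["mean_p"] <= 0.01 and r2["direction"] == "lower"
    with pytest.raises(ValueError, match="empty track"):
        track_signal_test(sites, const.iloc[0:0], mask, rng=rng)


def test_track_calibration(seq_world):
    genome, seqs, mask = seq_world
    rng0 = np.random.default_rng(31)
    noise = []
    for chrom, size in genome.chromosomes:
        edges = np.arange(0, size + 1, 1_000)
        vals = rng0.random(len(edges) - 1)
        noise.append(pd.DataFrame({"chrom": chrom, "start": edges[:-1],
                                   "end": edges[1:], "value": vals}))
    track = pd.concat(noise, ignore_index=True)
    ps = []
    for k in range(60):
        rng = np.random.default_rng(4000 + k)
        sites = _random_sites(mask, 25, 300, rng)
        ps.append(track_signal_test(sites, track, mask, n_background=300,
                                    rng=rng)["mean_p"])
    assert st.kstest(ps, "uniform").pvalue > 0.001


def test_annotation_enrichment_planted_and_strand(seq_world):
    genome, seqs, mask = seq_world
    rng = np.random.default_rng(3)
    plus = genome.genes[genome.genes["strand"] == "+"].head(30)
    sites = pd.DataFrame(
        {"chrom": plus["chrom"], "start": plus["start"] - 260,
         "end": plus["start"] - 240}
    ).reset_index(drop=True)
    res = annotation_enrichment(sites, genome, mask, n_iter=999, rng=rng)
    assert res["promoter"].p <= 0.01
    assert res["promoter"].observed == len(sites)
    # minus-strand gene: promoter lies downstream in genome coordinates
    minus = genome.genes[genome.genes["strand"] == "-"].head(30)
    sites_m = pd.DataFrame(
        {"chrom": minus["chrom"], "start": minus["end"] + 240,
         "end": minus["end"] + 260}
    ).reset_index(drop=True)
    res_m = annotation_enrichment(sites_m, genome, mask, n_iter=999, rng=rng)
    assert res_m["promoter"].observed == len(sites_m)


def test_annotation_enrichment_calibration(seq_world):
    genome, seqs, mask = seq_world
    ps = []
    for k in range(60):
        rng = np.random.default_rng(6000 + k)
        sites = _random_sites(mask, 25, 50, rng)
        res = annotation_enrichment(sites, genome, mask, n_iter=199, rng=rng)
        ps.append(res["promoter"].p)
    # two-sided discrete p-values are conservative; check they are not
    # anti-conservative at the 5% level
    assert np.mean(np.asarray(ps) <= 0.05) <= 0.10


# ---------------------------------------------------------------------------
# motifs


def test_pwm_threshold_properties():
    with pytest.raises(ValueError):
        pwm_score_threshold(np.empty((0, 4)))
    q, t1 = pwm_score_threshold(POLY_A_PWM, match_p=1e-3)
    _, t2 = pwm_score_threshold(POLY_A_PWM, match_p=1e-6)
    assert t2 > t1  # stricter p-value needs a higher score
    _, t_all = pwm_score_threshold(POLY_A_PWM, match_p=1.0)
    assert t_all == int(q.min(axis=1).sum())  # everything matches


def test_motif_planted_detected(seq_world):
    genome, seqs, mask = seq_world
    rng = np.random.default_rng(7)
    sites = _random_sites(mask, 30, 300, rng)
    seqs2 = dict(seqs)
    for row in sites.itertuples():
        plant_motif(seqs2, row.chrom, [row.start + 100], "A" * 14)
    res = motif_rescreen(
        POLY_A_PWM, sites, seqs2, mask, n_random=400, n_iter=499,
        match_p=1e-6, rng=rng,
    )
    assert res.p <= 0.01 and res.observed == len(sites)


def test_motif_null_calibration(seq_world):
    genome, seqs, mask = seq_world
    ps = []
    for k in range(40):
        rng = np.random.default_rng(8000 + k)
        sites = _random_sites(mask, 20, 200, rng)
        res = motif_rescreen(GAA_PWM, sites, seqs, mask, n_random=150,
                             n_iter=199, match_p=1e-4, rng=rng)
        ps.append(res.p)
    assert np.mean(np.asarray(ps) <= 0.05) <= 0.125
    assert np.mean(ps) > 0.3


def test_degenerate_threshold_saturates(seq_world):
    genome, seqs, mask = seq_world
    rng = np.random.default_rng(9)
    sites = _random_sites(mask, 10, 100, rng)
    res = motif_rescreen(POLY_A_PWM, sites, seqs, mask, n_random=50,
                         n_iter=99, match_p=1.0, rng=rng)
    assert res.observed == len(sites) and res.p == 1.0


# ---------------------------------------------------------------------------
# nucleosome exclusion


def test_exclusion_motif_regex_oracle():
    # hand-evaluated: [CG]{3} NN [CG]{3} NN [CG]{3} matches at position 0
    assert nucleosome_exclusion_sites("CCCAACCCTTGGG").tolist() == [6]
    assert len(nucleosome_exclusion_sites("A" * 10)) == 1
    assert len(nucleosome_exclusion_sites("T" * 10)) == 1  # both strands
    assert len(nucleosome_exclusion_sites("ACGT" * 10)) == 0


def test_distance_zero_inside_poly_a(seq_world):
    genome, seqs, mask = seq_world
    seqs2 = dict(seqs)
    plant_motif(seqs2, "c1", [10_000], "A" * 12)
    sites = pd.DataFrame({"chrom": ["c1"], "start": [10_004], "end": [10_008]})
    r = nucleosome_exclusion_distance(sites, seqs2, mask, n_background=200,
                                      rng=np.random.default_rng(0))
    assert r["site_distances"][0] == 0


def test_nucleosome_distance_planted_closer(seq_world):
    genome, seqs, mask = seq_world
    rng = np.random.default_rng(13)
    sites = _random_sites(mask, 30, 200, rng)
    seqs2 = dict(seqs)
    for row in sites.itertuples():
        plant_motif(seqs2, row.chrom, [row.start + 90], "A" * 12)
    r = nucleosome_exclusion_distance(sites, seqs2, mask, n_background=2_000,
                                      rng=rng)
    assert r["p"] <= 0.01 and r["direction"] == "closer"
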