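"""Generator contracts: marker construction, meiosis truth, read emission."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetrada._random import substream
from tetrada.genotyping import call_genotypes
from tetrada.af_model import CutoffModel
from tetrada.regions import positions_within
from tetrada.synthetic_data import (
    ArtifactSpec,
    SimulationConfig,
    build_genome,
    emit_allele_counts,
    simulate_cohort,
    simulate_meiosis,
    write_fixture,
)
from tetrada import io as tio


def test_marker_construction_contract():
    cfg = SimulationConfig(
        chromosomes=[("c1", 1_000_000)], markers_per_bp=1e-3, seed=1,
        triallelic_frac=0.0,
    )
    _, markers, _ = build_genome(cfg)
    assert 800 < len(markers) < 1200  # Poisson around 1000
    pos = markers["pos"].to_numpy()
    assert (np.diff(pos) > 0).all()
    assert (markers["allele_P1"] != markers["allele_P2"]).all()
    assert markers["allele_recipient"].isin(
        list(markers["allele_P1"]) + list(markers["allele_P2"])
    ).all()


def test_recipient_match_balance_binomial():
    cfg = SimulationConfig(
        chromosomes=[("c1", 10_000_000)], markers_per_bp=1e-3,
        recipient_match_p1=0.5, triallelic_frac=0.0, seed=7,
    )
    _, markers, _ = build_genome(cfg)
    n = len(markers)
    k = int((markers["recipient_class"] == 0).sum())
    lo, hi = stats.binom.interval(0.99, n, 0.5)
    assert lo <= k <= hi


def test_zero_density_chromosome_is_empty_not_error():
    cfg = SimulationConfig(chromosomes=[("c1", 1_000)], markers_per_bp=1e-9, seed=1)
    _, markers, _ = build_genome(cfg)
    assert len(markers) == 0 or (markers["chrom"] == "c1").all()


def test_zero_length_genome_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(chromosomes=[("c1", 0)]).validate()


def test_invalid_artifact_specs_rejected():
    with pytest.raises(ValueError):
        ArtifactSpec("nonsense", "c1", (0, 10))
    with pytest.raises(ValueError):
        ArtifactSpec("transposition_cnv", "c1", (0, 100), insertion_point=50)


def test_segregation_invariants(small_cohort):
    """Outside conversion tracts markers segregate 2:2; inside NCO tracts 3:1."""
    _, _, markers, truth, _ = small_cohort
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    for m in truth.meioses:
        paint = np.stack([m.paint[c] for c in range(4)])
        tr = pd.DataFrame(
            [(t.chrom, t.start, t.end) for t in m.tracts],
            columns=["chrom", "start", "end"],
        )
        inside = positions_within(chroms, pos, tr)
        seg = paint.sum(axis=0)
        assert (seg[~inside] == 2).all()
        # every NCO tract marker where conversion changed an allele is 3:1
        for t in m.tracts:
            sel = (chroms == t.chrom) & (pos >= t.start) & (pos < t.end)
            if sel.any():
                assert set(seg[sel]) <= {1, 2, 3}


def test_co_counts_poisson_at_shape_one():
    """Gamma shape 1 gives Poisson-like per-chromosome CO counts."""
    cfg = SimulationConfig(
        chromosomes=[("c1", 5_000_000)], co_per_meiosis_mean=3.0,
        interference_shape=1.0, obligate_co=False, n_dsb=0, markers_per_bp=1e-5,
        seed=5,
    )
    genome, markers, _ = build_genome(cfg)
    rng = substream(cfg.seed, "meio-test")
    counts = [
        len(simulate_meiosis(genome, markers, cfg, rng).cos) for _ in range(3000)
    ]
    counts = np.asarray(counts)
    ratio = counts.var() / counts.mean()
    assert abs(ratio - 1.0) < 0.15  # index of dispersion ~ 1 under Poisson
    assert abs(counts.mean() - 3.0) < 0.15


def test_interference_shortens_spacing_cv():
    def spacing_cv(shape, seed):
        cfg = SimulationConfig(
            chromosomes=[("c1", 5_000_000)], co_per_meiosis_mean=5.0,
            interference_shape=shape, obligate_co=False, n_dsb=0,
            markers_per_bp=1e-5, seed=seed,
        )
        genome, markers, _ = build_genome(cfg)
        rng = substream(seed, "cv")
        gaps = []
        for _ in range(400):
            m = simulate_meiosis(genome, markers, cfg, rng)
            p = sorted(c.pos for c in m.cos)
            gaps.extend(np.diff(p))
        gaps = np.asarray(gaps, dtype=float)
        return gaps.std() / gaps.mean()

    assert spacing_cv(10.0, 2) < spacing_cv(1.0, 2)


def test_nco_thinning_identity():
    """n_dsb=100, half restored, no COs -> mean 50 NCO tracts per meiosis."""
    cfg = SimulationConfig(
        chromosomes=[("c1", 5_000_000)], co_per_meiosis_mean=0.0,
        obligate_co=False, n_dsb=100, frac_dsb_restored=0.5,
        markers_per_bp=1e-5, seed=6,
    )
    genome, markers, _ = build_genome(cfg)
    rng = substream(6, "thin")
    n = [len(simulate_meiosis(genome, markers, cfg, rng).tracts) for _ in range(400)]
    se = np.std(n, ddof=1) / np.sqrt(len(n))
    assert abs(np.mean(n) - 50.0) < 4 * se


def test_tract_marker_coverage_expectation():
    """E[markers inside tracts] ~ n_tracts * length * density."""
    L, density = 200, 2e-3
    cfg = SimulationConfig(
        chromosomes=[("c1", 5_000_000)], co_per_meiosis_mean=0.0,
        obligate_co=False, n_dsb=40, frac_dsb_restored=0.0,
        ncoct_length_bp=float(L), markers_per_bp=density,
        pericentromere_frac=0.0, triallelic_frac=0.0, seed=8,
    )
    genome, markers, _ = build_genome(cfg)
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    rng = substream(8, "cov")
    per_rep = []
    for _ in range(300):
        m = simulate_meiosis(genome, markers, cfg, rng)
        k = 0
        for t in m.tracts:
            k += int(((chroms == t.chrom) & (pos >= t.start) & (pos < t.end)).sum())
        per_rep.append(k)
    expected = 40 * L * density
    se = np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))
    assert abs(np.mean(per_rep) - expected) < 3 * se + 0.5


def test_noiseless_counts_single_allele():
    cfg = SimulationConfig(
        chromosomes=[("c1", 500_000)], n_tetrads=0, n_dh=1, per_read_error=0.0,
        coverage_dispersion=0.0, markers_per_bp=5e-4, triallelic_frac=0.0, seed=4,
    )
    genome, markers, truth = simulate_cohort(cfg)
    counts = emit_allele_counts(truth, genome, markers, cfg, include_parents=False)
    # homozygous DH: every read carries the painted parent's allele
    mat = counts[["n_P1", "n_P2", "n_other"]].to_numpy()
    assert ((mat > 0).sum(axis=1) <= 1).all()


def test_het_offspring_mean_donor_frequency_half():
    cfg = SimulationConfig(
        chromosomes=[("c1", 5_000_000)], n_tetrads=1, n_dh=0,
        markers_per_bp=2e-3, per_read_error=0.0, triallelic_frac=0.0, seed=12,
    )
    genome, markers, truth = simulate_cohort(cfg)
    counts = emit_allele_counts(truth, genome, markers, cfg, include_parents=False)
    one = counts[counts["sample"] == "T1_1"].reset_index(drop=True)
    # heterozygous markers: recipient differs from the painted donor
    paint = truth.meioses[0].paint[0]
    het = markers["recipient_class"].to_numpy() != paint
    donor_n = np.where(paint[het] == 0, one.loc[het, "n_P1"], one.loc[het, "n_P2"])
    depth = one.loc[het, "depth"].to_numpy()
    frac = donor_n.sum() / depth.sum()
    se = 0.5 / np.sqrt(depth.sum())
    assert abs(frac - 0.5) < 4 * se


def test_cnv_duplication_shows_both_alleles(artifact_cohort):
    """A product carrying both transposed copies shows P1 and P2 alleles."""
    _, _, markers, truth, counts = artifact_cohort
    dup = [
        (s, x) for s, v in truth.cnv.items() for x in v if x[4] == 2
    ]
    assert dup, "fixture should contain a duplicated product"
    sample, (_, chrom, s, e, _) = dup[0][0], dup[0][1]
    sub = counts[
        (counts["sample"] == sample)
        & (counts["chrom"] == chrom)
        & (counts["pos"] >= s)
        & (counts["pos"] < e)
    ].merge(markers[["chrom", "pos", "triallelic"]], on=["chrom", "pos"])
    sub = sub[~sub["triallelic"]]
    both = ((sub["n_P1"] >= 3) & (sub["n_P2"] >= 3)).mean()
    assert both > 0.9


def test_naive_caller_reproduces_truth_paint():
    """With no artifacts and no read error, calls equal the truth paint."""
    cfg = SimulationConfig(
        chromosomes=[("c1", 1_000_000)], n_tetrads=1, n_dh=0,
        markers_per_bp=1e-3, per_read_error=0.0, coverage_mean=80,
        triallelic_frac=0.0, seed=21,
    )
    genome, markers, truth = simulate_cohort(cfg)
    counts = emit_allele_counts(truth, genome, markers, cfg, include_parents=False)
    calls = call_genotypes(counts, markers, CutoffModel.fixed(0.9), min_cov=10)
    for c in range(4):
        sample = f"T1_{c + 1}"
        sub = calls[calls["sample"] == sample].reset_index(drop=True)
        ok = sub["donor"] >= 0
        assert ok.mean() > 0.95
        assert (sub.loc[ok, "donor"].to_numpy() == truth.meioses[0].paint[c][ok]).all()


def test_fixture_round_trip(tmp_path, small_cohort):
    _, genome, markers, truth, counts = small_cohort
    write_fixture(tmp_path, genome, markers, counts, truth)
    m2 = tio.read_marker_table(tmp_path / "markers.tsv")
    c2 = tio.read_allele_counts(tmp_path / "allele_counts.tsv")
    t2 = tio.read_truth(tmp_path / "truth.json")
    g2 = tio.read_genome_model(tmp_path)
    pd.testing.assert_frame_equal(markers.reset_index(drop=True), m2[markers.columns])
    pd.testing.assert_frame_equal(counts.reset_index(drop=True), c2[counts.columns])
    assert g2.chromosomes == genome.chromosomes
    assert g2.pericentromere == genome.pericentromere
    for m, m_back in zip(truth.meioses, t2.meioses):
        assert [ (c.chrom, c.pos, tuple(c.chromatids)) for c in m.cos ] == \
               [ (c.chrom, c.pos, tuple(c.chromatids)) for c in m_back.cos ]
        for c in range(4):
            assert (m.paint[c] == m_back.paint[c]).all()
        # reciprocity is re-verifiable on the re-ingested truth
        seg = np.stack([m_back.paint[c] for c in range(4)]).sum(axis=0)
        assert set(np.unique(seg)) <= {1, 2, 3}


def test_empty_marker_fixture_round_trip(tmp_path):
    cfg = SimulationConfig(
        chromosomes=[("c1", 10_000)], markers_per_bp=1e-9, n_tetrads=0, n_dh=0,
        seed=1,
    )
    genome, markers, truth = simulate_cohort(cfg)
    counts = emit_allele_counts(truth, genome, markers, cfg)
    write_fixture(tmp_path, genome, markers, counts, truth)
    assert len(tio.read_marker_table(tmp_path / "markers.tsv")) == len(markers)


def test_seed_reproducibility():
    cfg = SimulationConfig(chromosomes=[("c1", 500_000)], n_tetrads=1, n_dh=1,
                           markers_per_bp=1e-3, seed=99)
    g1, m1, t1 = simulate_cohort(cfg)
    g2, m2, t2 = simulate_cohort(cfg)
    pd.testing.assert_frame_equal(m1, m2)
    for a, b in zip(t1.meioses, t2.meioses):
        assert [(c.chrom, c.pos) for c in a.cos] == [(c.chrom, c.pos) for c in b.cos]
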