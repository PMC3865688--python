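"""Shared fixtures: all data is generated programmatically at test time."""

import numpy as np
import pytest

from tetrada.synthetic_data import (
    ArtifactSpec,
    SimulationConfig,
    emit_allele_counts,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Two tetrads + two DH lines on a compact two-chromosome genome."""
    cfg = SimulationConfig(
        chromosomes=[("chr1", 2_000_000), ("chr2", 2_000_000)],
        n_tetrads=2,
        n_dh=2,
        markers_per_bp=1e-3,
        seed=3,
    )
    genome, markers, truth = simulate_cohort(cfg)
    counts = emit_allele_counts(truth, genome, markers, cfg)
    return cfg, genome, markers, truth, counts


@pytest.fixture(scope="session")
def study_cohort():
    """Study-scale clean fixture: 5 tetrads, 5 x 5 Mb, density 2e-3,
    coverage 60x, per-read error 0.5%."""
    cfg = SimulationConfig(n_tetrads=5, n_dh=0, seed=42)
    genome, markers, truth = simulate_cohort(cfg)
    counts = emit_allele_counts(truth, genome, markers, cfg)
    return cfg, genome, markers, truth, counts


@pytest.fixture(scope="session")
def artifact_cohort():
    """Same study conditions with a triple-haplotype repeat and an 80 kb
    transposition CNV injected."""
    arts = [
        ArtifactSpec("triple_haplotype", "chr1", (1_000_000, 1_040_000)),
        ArtifactSpec(
            "transposition_cnv", "chr3", (3_600_000, 3_680_000),
            insertion_point=4_300_000,
        ),
    ]
    cfg = SimulationConfig(n_tetrads=5, n_dh=0, seed=43, artifact_loci=arts)
    genome, markers, truth = simulate_cohort(cfg)
    counts = emit_allele_counts(truth, genome, markers, cfg)
    return cfg, genome, markers, truth, counts


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
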