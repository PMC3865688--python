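#!/usr/bin/env python
"""Generate the synthetic study cohorts and write them as fixtures.

Produces two cohorts under results/fixtures/: a clean one (5 tetrads + 10
DH lines, 5 x 5 Mb genome, marker density 2e-3/bp, 60x coverage, 0.5%
per-read error) and one with structural-variant artifacts injected (a
triple-haplotype repeat and an 80 kb transposition CNV), together with the
full ground truth used by the downstream checks.
"""

import argparse
from pathlib import Path

from tetrada.synthetic_data import (
    ArtifactSpec,
    SimulationConfig,
    emit_allele_counts,
    simulate_cohort,
    write_fixture,
)

ROOT = Path(__file__).resolve().parents[1]


def make_configs(seed: int):
    clean = SimulationConfig(n_tetrads=5, n_dh=10, seed=seed)
    arts = [
        ArtifactSpec("triple_haplotype", "chr1", (1_000_000, 1_040_000)),
        ArtifactSpec(
            "transposition_cnv", "chr3", (3_600_000, 3_680_000),
            insertion_point=4_300_000,
        ),
    ]
    artifact = SimulationConfig(n_tetrads=5, n_dh=0, seed=seed + 1, artifact_loci=arts)
    return {"clean": clean, "artifact": artifact}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "fixtures")
    args = ap.parse_args()
    for name, cfg in make_configs(args.seed).items():
        genome, markers, truth = simulate_cohort(cfg)
        counts = emit_allele_counts(truth, genome, markers, cfg)
        outdir = args.out / name
        write_fixture(outdir, genome, markers, counts, truth)
        n_cos = sum(len(m.cos) for m in truth.meioses)
        n_nco = sum(
            1 for m in truth.meioses for t in m.tracts if t.kind == "NCO_GC"
        )
        print(
            f"[{name}] {len(markers)} markers, {len(truth.meioses)} tetrads, "
            f"{len(truth.dh)} DH lines, {n_cos} tetrad COs, {n_nco} NCO tracts "
            f"-> {outdir}"
        )


if __name__ == "__main__":
    main()
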