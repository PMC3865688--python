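"""Synthetic tetrad / doubled-haploid sequencing data with ground truth.

The generator emulates the structure of a tetrad-resequencing experiment:
two inbred donor parents (P1, P2: think Col and Ler) are crossed, the F1
undergoes meiosis, and each of the four meiotic products is recovered either
as a tetrad offspring (one recombinant haplotype plus one haplotype from a
third "recipient" parent, Cvi) or as a fully homozygous doubled-haploid (DH)
line.  Crossovers are reciprocal exchanges between one chromatid of each
homolog; gene conversions copy a short tract from the homolog onto one
chromatid, producing 3:1 marker segregation across the four products.

Two classes of alignment artifact can be injected, mirroring the failure
modes that confound short-read GC detection:

* ``triple_haplotype`` -- a diverged repeat makes a third haplotype align
  over an interval: a constant fraction of decoy reads is added to every
  sample (parents included), so inbred parents appear heterozygous and
  homozygous offspring markers look like conversions (a type-1 excess).
* ``transposition_cnv`` -- sequence present at different locations in the
  two parents; a crossover between the two sites leaves one product with
  zero copies and the reciprocal product with two, so read counts inside the
  interval show both parental alleles (two copies) or only the recipient
  allele (zero copies).

All coordinates are 0-based half-open internally; writers emit 1-based
inclusive positions (VCF/BED conventions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from tetrada._random import substream
from tetrada.regions import MASK_COLUMNS, complement, sample_positions

BASES = np.array(list("ACGT"))

MARKER_COLUMNS = [
    "chrom",
    "pos",
    "allele_P1",
    "allele_P2",
    "allele_recipient",
    "recipient_class",
    "quality",
    "triallelic",
    "decoy",
]

COUNT_COLUMNS = ["sample", "chrom", "pos", "n_P1", "n_P2", "n_other", "depth"]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GenomeModel:
    """Chromosome sizes, peri-centromeres and annotation tracks."""

    chromosomes: list[tuple[str, int]]
    pericentromere: dict[str, tuple[int, int]]
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    transposons: pd.DataFrame = field(default_factory=pd.DataFrame)
    duplications: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        sizes = self.chrom_sizes()
        for name, size in self.chromosomes:
            if size <= 0:
                raise ValueError(f"zero-length chromosome {name}")
        for name, (s, e) in self.pericentromere.items():
            if name not in sizes:
                raise ValueError(f"pericentromere on unknown chromosome {name}")
            if not (0 <= s < e <= sizes[name]):
                raise ValueError(f"pericentromere outside chromosome {name}")
        for df in (self.genes, self.transposons, self.duplications):
            if len(df):
                bad = (df["start"] < 0) | (df["end"] > df["chrom"].map(sizes))
                if bad.any():
                    raise ValueError("annotation interval outside chromosome bounds")

    def chrom_sizes(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def pericentromere_frame(self) -> pd.DataFrame:
        rows = [(c, s, e) for c, (s, e) in self.pericentromere.items()]
        return pd.DataFrame(rows, columns=MASK_COLUMNS)

    def arm_mask(self) -> pd.DataFrame:
        """Non-peri-centromeric regions (the background-sampling mask)."""
        return complement(self.pericentromere_frame(), self.chrom_sizes())


@dataclass
class ArtifactSpec:
    """A structural-variant locus that corrupts short-read allele counts."""

    kind: str  # "triple_haplotype" | "transposition_cnv"
    chrom: str
    source_interval: tuple[int, int]
    insertion_point: int | None = None  # transposition_cnv only
    affected_parent: int = 1  # parent carrying the sequence at the insertion
    decoy_fraction: float = 1.0 / 3.0  # triple_haplotype read contamination
    sentinel_spacing: int = 200  # recipient-informative site density inside

    def __post_init__(self):
        if self.kind not in ("triple_haplotype", "transposition_cnv"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        s, e = self.source_interval
        if not s < e:
            raise ValueError("empty artifact interval")
        if self.kind == "transposition_cnv":
            if self.insertion_point is None:
                raise ValueError("transposition_cnv needs an insertion_point")
            if s <= self.insertion_point < e:
                raise ValueError("transposition source and insertion overlap")


def _dist_spec(spec) -> tuple[float, float]:
    """Normalize a length-distribution spec: scalar -> (mean, 0)."""
    if np.isscalar(spec):
        return float(spec), 0.0
    mean, sd = spec
    return float(mean), float(sd)


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults follow the experiment the pipeline is built for: ~10 COs per
    meiosis, CO conversion tracts of ~300-400 bp present at 62% of COs,
    NCO tracts of 25-50 bp arising from ~100 DSBs per meiosis of which half
    restore the original allele, ~50-60x coverage.
    """

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [(f"chr{i}", 5_000_000) for i in range(1, 6)]
    )
    pericentromere_frac: float = 0.2
    n_tetrads: int = 5
    n_dh: int = 10
    markers_per_bp: float = 2e-3
    triallelic_frac: float = 0.02  # recipient-informative sentinel sites
    recipient_match_p1: float = 0.5
    co_per_meiosis_mean: float = 10.0
    interference_shape: float = 1.0  # gamma shape of inter-CO spacing
    obligate_co: bool = True
    co_gc_prob: float = 0.62
    coct_length_bp: tuple | float = (350.0, 50.0)
    ncoct_length_bp: tuple | float = (37.0, 12.0)
    n_dsb: int = 100
    frac_dsb_restored: float = 0.5
    coverage_mean: float = 60.0
    coverage_dispersion: float = 0.1
    per_read_error: float = 0.005
    marker_quality: int = 40
    gc_fraction: float = 0.36
    artifact_loci: list[ArtifactSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self):
        for p, name in [
            (self.frac_dsb_restored, "frac_dsb_restored"),
            (self.per_read_error, "per_read_error"),
            (self.co_gc_prob, "co_gc_prob"),
            (self.recipient_match_p1, "recipient_match_p1"),
            (self.triallelic_frac, "triallelic_frac"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for r, name in [
            (self.markers_per_bp, "markers_per_bp"),
            (self.co_per_meiosis_mean, "co_per_meiosis_mean"),
            (self.coverage_mean, "coverage_mean"),
        ]:
            if r < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.interference_shape <= 0:
            raise ValueError("interference_shape must be positive")
        if not self.chromosomes or all(s <= 0 for _, s in self.chromosomes):
            raise ValueError("genome has no sequence")
        return self


@dataclass
class Crossover:
    chrom: str
    pos: int
    chromatids: tuple[int, int]  # one of (0,1) x one of (2,3)


@dataclass
class Tract:
    """A conversion tract on one chromatid, converted to ``to_parent``."""

    kind: str  # "NCO_GC" | "CO_GC"
    chrom: str
    start: int
    end: int
    chromatid: int
    to_parent: int
    co_index: int | None = None  # CO_GC: index into MeiosisTruth.cos


@dataclass
class MeiosisTruth:
    name: str
    cos: list[Crossover]
    tracts: list[Tract]
    # chromatid (0..3) -> donor parent (0/1) at every marker (global index)
    paint: dict[int, np.ndarray]

    def chromatid_parent(self, chromatid: int) -> int:
        return 0 if chromatid < 2 else 1


@dataclass
class DHTruth:
    sample: str
    meiosis: MeiosisTruth
    gamete: int  # which chromatid became the DH line


@dataclass
class TetradTruth:
    """Ground truth for a simulated cohort."""

    meioses: list[MeiosisTruth]  # complete tetrads
    dh: list[DHTruth]
    # sample -> list of (artifact_index, chrom, start, end, copies)
    cnv: dict[str, list[tuple[int, str, int, int, int]]] = field(default_factory=dict)

    def tetrad_samples(self) -> list[str]:
        return [f"{m.name}_{c + 1}" for m in self.meioses for c in range(4)]

    def sample_paint(self, sample: str) -> np.ndarray:
        for m in self.meioses:
            for c in range(4):
                if f"{m.name}_{c + 1}" == sample:
                    return m.paint[c]
        for d in self.dh:
            if d.sample == sample:
                return d.meiosis.paint[d.gamete]
        raise KeyError(sample)


# ---------------------------------------------------------------------------
# genome + markers


def _random_annotations(genome_chroms, pericent, rng) -> dict[str, pd.DataFrame]:
    """Sprinkle genes (with strand), transposons and duplications."""
    genes, tes, dups = [], [], []
    for chrom, size in genome_chroms:
        pos = 1000
        while pos + 3000 < size:
            length = int(rng.integers(800, 3000))
            if rng.random() < 0.6:
                genes.append((chrom, pos, pos + length, "+" if rng.random() < 0.5 else "-"))
            pos += length + int(rng.integers(500, 4000))
        if size < 20_000:
            continue  # too small for repeat annotations
        ps, pe = pericent.get(chrom, (size // 2, size // 2 + 1))
        n_te = max(1, int((size / 1e6)))
        for _ in range(n_te):
            if rng.random() < 0.7:  # transposons favour the pericentromere
                s = int(rng.integers(ps, max(ps + 1, pe - 5000)))
            else:
                s = int(rng.integers(0, size - 5000))
            tes.append((chrom, s, min(size, s + int(rng.integers(500, 5000)))))
        for _ in range(max(1, n_te // 2)):
            s = int(rng.integers(0, size - 8000))
            dups.append((chrom, s, s + int(rng.integers(1000, 8000))))
    return {
        "genes": pd.DataFrame(genes, columns=["chrom", "start", "end", "strand"]),
        "transposons": pd.DataFrame(tes, columns=MASK_COLUMNS),
        "duplications": pd.DataFrame(dups, columns=MASK_COLUMNS),
    }


def build_genome(config: SimulationConfig, with_sequence: bool = False):
    """Construct the genome model, marker table and (optionally) sequence.

    Markers are a Poisson process of density ``markers_per_bp`` per
    chromosome; each carries two distinct parental alleles and a recipient
    allele equal to P1's with probability ``recipient_match_p1`` (otherwise
    P2's), except a ``triallelic_frac`` fraction of recipient-informative
    sites where the recipient carries a third allele.  Artifact loci receive
    additional densified recipient-informative sites, emulating the local
    divergence of rearranged sequence.

    Returns ``(genome, markers, sequences)``; ``sequences`` is a dict
    chrom -> str or None.
    """
    config.validate()
    if config.markers_per_bp <= 0:
        raise ValueError("marker density must be > 0")
    rng = substream(config.seed, "genome")
    pericent = {}
    for chrom, size in config.chromosomes:
        half = int(size * config.pericentromere_frac / 2)
        if half > 0:
            mid = size // 2
            pericent[chrom] = (mid - half, mid + half)
    ann = _random_annotations(config.chromosomes, pericent, rng)
    genome = GenomeModel(
        chromosomes=list(config.chromosomes),
        pericentromere=pericent,
        genes=ann["genes"],
        transposons=ann["transposons"],
        duplications=ann["duplications"],
    )

    frames = []
    for chrom, size in config.chromosomes:
        n = rng.poisson(size * config.markers_per_bp)
        pos = np.sort(rng.choice(size, size=min(n, size), replace=False))
        frames.append(
            pd.DataFrame({"chrom": chrom, "pos": pos, "force_triallelic": False})
        )
    # densified sentinel sites inside artifact intervals
    for art in config.artifact_loci:
        s, e = art.source_interval
        pos = np.arange(s + art.sentinel_spacing // 2, e, art.sentinel_spacing)
        frames.append(
            pd.DataFrame({"chrom": art.chrom, "pos": pos, "force_triallelic": True})
        )
    markers = pd.concat(frames, ignore_index=True)
    markers["force_triallelic"] = markers["force_triallelic"].astype(bool)
    markers = (
        markers.sort_values(
            ["chrom", "pos", "force_triallelic"], ascending=[True, True, False]
        )
        .drop_duplicates(["chrom", "pos"])
        .reset_index(drop=True)
    )

    n = len(markers)
    a1 = rng.integers(0, 4, size=n)
    a2 = (a1 + rng.integers(1, 4, size=n)) % 4  # distinct from a1
    third = np.array(
        [
            (set(range(4)) - {i, j}).pop()
            for i, j in zip(a1 % 4, a2 % 4)
        ]
    ) if n else np.array([], dtype=int)
    triallelic = markers["force_triallelic"].to_numpy() | (
        rng.random(n) < config.triallelic_frac
    )
    match_p1 = rng.random(n) < config.recipient_match_p1
    recipient_class = np.where(triallelic, 2, np.where(match_p1, 0, 1))
    recip = np.where(
        recipient_class == 0, a1, np.where(recipient_class == 1, a2, third)
    )
    markers["allele_P1"] = BASES[a1]
    markers["allele_P2"] = BASES[a2]
    markers["allele_recipient"] = BASES[recip] if n else []
    markers["recipient_class"] = recipient_class.astype(np.int8)
    markers["quality"] = config.marker_quality
    markers["triallelic"] = triallelic
    markers["decoy"] = np.int8(-1)
    markers = markers.drop(columns=["force_triallelic"])

    # decoy haplotype alleles for triple_haplotype artifacts
    for art in config.artifact_loci:
        if art.kind != "triple_haplotype":
            continue
        s, e = art.source_interval
        sel = (
            (markers["chrom"] == art.chrom)
            & (markers["pos"] >= s)
            & (markers["pos"] < e)
        ).to_numpy()
        k = int(sel.sum())
        # decoy mostly mirrors a diverged second parental copy: it carries
        # P1/P2 alleles plus novel ones, which is what makes inbred parents
        # look heterozygous and creates three-haplotype evidence
        markers.loc[sel, "decoy"] = rng.choice(
            np.array([0, 1, 2], dtype=np.int8), size=k, p=[0.35, 0.35, 0.30]
        )

    sequences = None
    if with_sequence:
        sequences = build_sequences(genome, config.gc_fraction, rng)
    return genome, markers, sequences


def build_sequences(genome: GenomeModel, gc_fraction: float, rng) -> dict[str, str]:
    p_gc = gc_fraction / 2
    p_at = (1 - gc_fraction) / 2
    out = {}
    for chrom, size in genome.chromosomes:
        arr = rng.choice(BASES, size=size, p=[p_at, p_gc, p_gc, p_at])
        out[chrom] = "".join(arr)
    return out


def plant_motif(sequences: dict[str, str], chrom: str, positions, motif: str):
    """Overwrite the sequence with ``motif`` at each position (in place)."""
    seq = list(sequences[chrom])
    for p in positions:
        seq[p : p + len(motif)] = motif
    sequences[chrom] = "".join(seq)


# ---------------------------------------------------------------------------
# meiosis


def _chrom_slices(markers: pd.DataFrame) -> dict[str, slice]:
    out = {}
    chroms = markers["chrom"].to_numpy()
    start = 0
    for chrom, grp in markers.groupby("chrom", sort=False):
        out[chrom] = slice(start, start + len(grp))
        start += len(grp)
    assert start == len(markers)
    return out


def _draw_length(spec, rng) -> int:
    mean, sd = _dist_spec(spec)
    if sd <= 0:
        return max(1, int(round(mean)))
    return max(1, int(round(rng.normal(mean, sd))))


def _renewal_positions(length, mean_count, shape, rng):
    """Stationary gamma-renewal event positions on [0, length)."""
    if mean_count <= 0:
        return []
    mu = length / mean_count
    if mu < 1.0:
        raise ValueError("crossover rate too high: mean spacing below 1 bp")
    scale = mu / shape
    # burn in from far left so the process is stationary over the chromosome
    x = -10.0 * mu + rng.random() * mu
    out = []
    while True:
        x += rng.gamma(shape, scale)
        if x >= length:
            break
        if x >= 0:
            out.append(int(x))
    return out


def simulate_meiosis(
    genome: GenomeModel,
    markers: pd.DataFrame,
    config: SimulationConfig,
    rng,
    name: str = "T1",
) -> MeiosisTruth:
    """Simulate one meiosis: COs, CO-associated GC tracts and NCO tracts.

    Chromatids 0,1 derive from parent P1, chromatids 2,3 from P2.  Each CO
    exchanges the distal arms of one chromatid of each homolog, so every
    marker outside a conversion tract segregates 2:2.  Inter-CO spacing is a
    stationary gamma renewal process (shape 1 = no interference).  NCO tract
    count per meiosis is ``n_dsb`` minus realized COs, thinned by
    ``frac_dsb_restored``; tracts land uniformly on the chromosome arms.
    """
    sizes = genome.chrom_sizes()
    total = sum(sizes.values())
    slices = _chrom_slices(markers)
    pos_by_chrom = {c: markers["pos"].to_numpy()[s] for c, s in slices.items()}

    paint = {c: np.empty(len(markers), dtype=np.int8) for c in range(4)}
    for c in range(4):
        paint[c][:] = 0 if c < 2 else 1

    cos: list[Crossover] = []
    tracts: list[Tract] = []
    for chrom, size in genome.chromosomes:
        expected = config.co_per_meiosis_mean * size / total
        for _ in range(1000):
            positions = _renewal_positions(
                size, expected, config.interference_shape, rng
            )
            if positions or not config.obligate_co:
                break
        sl = slices.get(chrom)
        mpos = pos_by_chrom.get(chrom, np.array([], dtype=int))
        sub = {c: paint[c][sl] for c in range(4)} if sl is not None else None
        # trace products through the CO junctions: a CO joins one strand of
        # each homolog, and the two products traversing those strands at that
        # position swap strands (and therefore donor parent) from there on
        strand_to_prod = [0, 1, 2, 3]
        chrom_cos = []
        transitions: dict[int, list[int]] = {c: [] for c in range(4)}
        for p in sorted(positions):
            i = int(rng.integers(0, 2))
            j = int(2 + rng.integers(0, 2))
            pi, pj = strand_to_prod[i], strand_to_prod[j]
            strand_to_prod[i], strand_to_prod[j] = pj, pi
            chrom_cos.append(Crossover(chrom, p, (pi, pj)))
            transitions[pi].append(p)
            transitions[pj].append(p)
        if sub is not None:
            for c in range(4):
                flips = np.searchsorted(np.asarray(transitions[c]), mpos, side="right")
                sub[c][:] = ((0 if c < 2 else 1) + flips) % 2
        # CO-associated conversion tracts, applied after all exchanges
        for k, co in enumerate(chrom_cos):
            if rng.random() >= config.co_gc_prob:
                continue
            L = _draw_length(config.coct_length_bp, rng)
            u = rng.random()
            s = max(0, int(co.pos - u * L))
            e = min(size, s + L)
            chromatid = co.chromatids[int(rng.integers(0, 2))]
            to_parent = int(rng.integers(0, 2))
            if sub is not None:
                lo = np.searchsorted(mpos, s)
                hi = np.searchsorted(mpos, e)
                sub[chromatid][lo:hi] = to_parent
            tracts.append(
                Tract("CO_GC", chrom, s, e, chromatid, to_parent, co_index=len(cos) + k)
            )
        cos.extend(chrom_cos)

    # NCO tracts
    n_potential = max(0, config.n_dsb - len(cos))
    n_keep = rng.binomial(n_potential, 1.0 - config.frac_dsb_restored)
    if n_keep > 0:
        arm = genome.arm_mask()
        chroms, centers = sample_positions(arm, int(n_keep), rng)
        for chrom, center in zip(chroms, centers):
            L = _draw_length(config.ncoct_length_bp, rng)
            s = max(0, int(center - L // 2))
            e = min(sizes[chrom], s + L)
            chromatid = int(rng.integers(0, 4))
            sl = slices.get(chrom)
            mpos = pos_by_chrom.get(chrom, np.array([], dtype=int))
            lo = np.searchsorted(mpos, s)
            hi = np.searchsorted(mpos, e)
            if sl is not None and hi > lo:
                sub = paint[chromatid][sl]
                to_parent = int(1 - sub[lo])
                sub[lo:hi] = to_parent
            else:
                to_parent = int(1 - (0 if chromatid < 2 else 1))
            tracts.append(Tract("NCO_GC", chrom, int(s), int(e), chromatid, to_parent))

    return MeiosisTruth(name=name, cos=cos, tracts=tracts, paint=paint)


def haplotype_at(meiosis: MeiosisTruth, chrom: str, pos: int) -> np.ndarray:
    """Donor parent of each product at an arbitrary position (COs only).

    ``Crossover.chromatids`` records the two products whose donor parent
    flips at the breakpoint, so the parent at ``pos`` is the starting parent
    plus the number of upstream flips, mod 2.
    """
    hap = np.array([0, 0, 1, 1], dtype=np.int8)
    for co in meiosis.cos:
        if co.chrom == chrom and co.pos <= pos:
            for c in co.chromatids:
                hap[c] = 1 - hap[c]
    return hap


def _cnv_copies(meiosis: MeiosisTruth, art: ArtifactSpec) -> np.ndarray:
    """Copy number of the transposed sequence per chromatid (0, 1 or 2)."""
    src_parent = 1 - art.affected_parent
    s, e = art.source_interval
    at_src = haplotype_at(meiosis, art.chrom, (s + e) // 2)
    at_ins = haplotype_at(meiosis, art.chrom, art.insertion_point)
    return (at_src == src_parent).astype(int) + (at_ins == art.affected_parent).astype(int)


def simulate_cohort(config: SimulationConfig):
    """Run the full generator: genome, markers, meioses, truth.

    Returns ``(genome, markers, truth)``.  Tetrad meioses are named
    ``T1..Tn``; DH lines ``DH1..DHm`` (each from its own meiosis, keeping a
    single random gamete).
    """
    genome, markers, _ = build_genome(config)
    rng = substream(config.seed, "meiosis")
    meioses = [
        simulate_meiosis(genome, markers, config, rng, name=f"T{t + 1}")
        for t in range(config.n_tetrads)
    ]
    dh = []
    for j in range(config.n_dh):
        m = simulate_meiosis(genome, markers, config, rng, name=f"DHM{j + 1}")
        dh.append(DHTruth(sample=f"DH{j + 1}", meiosis=m, gamete=int(rng.integers(0, 4))))
    truth = TetradTruth(meioses=meioses, dh=dh)
    for ai, art in enumerate(config.artifact_loci):
        if art.kind != "transposition_cnv":
            continue
        s, e = art.source_interval
        for m in truth.meioses:
            copies = _cnv_copies(m, art)
            for c in range(4):
                truth.cnv.setdefault(f"{m.name}_{c + 1}", []).append(
                    (ai, art.chrom, s, e, int(copies[c]))
                )
        for d in truth.dh:
            copies = _cnv_copies(d.meiosis, art)
            truth.cnv.setdefault(d.sample, []).append(
                (ai, art.chrom, s, e, int(copies[d.gamete]))
            )
    return genome, markers, truth


# ---------------------------------------------------------------------------
# read counts


def _nb_depth(mean, dispersion, size_n, rng):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size_n,))
    out = np.zeros(size_n, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 1e-9:
        out[pos] = rng.poisson(mean[pos])
    else:
        nb_n = 1.0 / dispersion
        p = nb_n / (nb_n + mean[pos])
        out[pos] = rng.negative_binomial(nb_n, p)
    return out


def _multinomial3(depth, probs, rng):
    """Row-wise multinomial over 3 classes; probs is (n, 3)."""
    p0 = probs[:, 0]
    p1 = probs[:, 1]
    n0 = rng.binomial(depth, np.clip(p0, 0, 1))
    rest = depth - n0
    denom = np.clip(1.0 - p0, 1e-12, None)
    n1 = rng.binomial(rest, np.clip(p1 / denom, 0, 1))
    n2 = rest - n1
    return n0, n1, n2


def _apply_error(probs, e):
    """Per-read error flips an observed allele to one of the other two."""
    return probs * (1 - e) + (1 - probs) * (e / 2.0)


def emit_allele_counts(
    truth: TetradTruth,
    genome: GenomeModel,
    markers: pd.DataFrame,
    config: SimulationConfig,
    include_parents: bool = True,
) -> pd.DataFrame:
    """Per-sample, per-marker allele counts (the short-read summary).

    Depth is negative-binomial with mean ``coverage_mean`` (scaled by local
    ploidy inside CNV intervals); reads come from the alleles on the
    sample's haplotypes with per-read error; artifact loci add decoy reads
    or CNV-driven allele mixtures.  Columns: sample, chrom, pos, n_P1, n_P2,
    n_other, depth.
    """
    rng = substream(config.seed, "counts")
    n = len(markers)
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    recipient_class = markers["recipient_class"].to_numpy()
    decoy = markers["decoy"].to_numpy()
    e = config.per_read_error
    decoy_art = [a for a in config.artifact_loci if a.kind == "triple_haplotype"]

    def _cnv_adjust(sample, hap_classes):
        """Rewrite haplotype copies inside CNV intervals (class -1 = absent)."""
        for _ai, chrom, s, e_, copies in truth.cnv.get(sample, []):
            sel = (chroms == chrom) & (pos >= s) & (pos < e_)
            if copies == 1 or not sel.any():
                continue
            hap_classes[0] = hap_classes[0].copy()
            if copies == 0:
                hap_classes[0][sel] = -1  # recombinant copy lost
            elif copies == 2:
                # both parental versions present on the recombinant side
                extra = np.full(n, -1, dtype=np.int8)
                extra[sel] = 0
                hap_classes[0][sel] = 1
                hap_classes.append(extra)
        return hap_classes

    def _emit(sample, hap_classes, baseline):
        """baseline = haplotype count carrying ``coverage_mean`` in total."""
        probs = np.zeros((n, 3))
        active = np.zeros(n)
        for hc in hap_classes:
            for cls in range(3):
                probs[:, cls] += hc == cls
            active += hc >= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = np.where(active[:, None] > 0, probs / active[:, None], 0.0)
        depth = _nb_depth(
            config.coverage_mean * active / baseline, config.coverage_dispersion, n, rng
        )
        pe = _apply_error(probs, e)
        pe[active == 0] = 0.0
        n0, n1, n2 = _multinomial3(depth, pe, rng)
        df = pd.DataFrame(
            {
                "sample": sample,
                "chrom": chroms,
                "pos": pos,
                "n_P1": n0,
                "n_P2": n1,
                "n_other": n2,
                "depth": depth,
            }
        )
        return _add_decoy(df, decoy_art, decoy, config, rng)

    frames = []
    for m in truth.meioses:
        for c in range(4):
            sample = f"{m.name}_{c + 1}"
            haps = _cnv_adjust(sample, [m.paint[c].copy(), recipient_class.copy()])
            frames.append(_emit(sample, haps, baseline=2))
    for d in truth.dh:
        haps = _cnv_adjust(d.sample, [d.meiosis.paint[d.gamete].copy()])
        frames.append(_emit(d.sample, haps, baseline=1))
    if include_parents:
        for sample, cls in [("P1", 0), ("P2", 1)]:
            hap = np.full(n, cls, dtype=np.int8)
            frames.append(_emit(sample, [hap, hap], baseline=2))
        hap = recipient_class.astype(np.int8)
        frames.append(_emit("CVI", [hap, hap], baseline=2))
    return pd.concat(frames, ignore_index=True)


def _add_decoy(df, decoy_art, decoy, config, rng):
    for art in decoy_art:
        f = art.decoy_fraction
        sel = decoy >= 0
        if not sel.any() or f <= 0:
            continue
        extra = np.zeros(len(df), dtype=np.int64)
        extra[sel] = rng.poisson(config.coverage_mean * f / (1 - f), size=int(sel.sum()))
        dprob = np.zeros((len(df), 3))
        dprob[np.arange(len(df)), np.clip(decoy, 0, 2)] = 1.0
        d0, d1, d2 = _multinomial3(extra, _apply_error(dprob, config.per_read_error), rng)
        df["n_P1"] = df["n_P1"].to_numpy() + d0
        df["n_P2"] = df["n_P2"].to_numpy() + d1
        df["n_other"] = df["n_other"].to_numpy() + d2
        df["depth"] = df["depth"].to_numpy() + extra
    return df


def simulate_dh_mutation_counts(
    n_sites: int,
    samples: list[str],
    mutations: list[tuple[int, str]],
    coverage: float = 50.0,
    error: float = 0.005,
    rng=None,
    score: int = 40,
) -> pd.DataFrame:
    """Counts at homozygous assayable sites for spontaneous-mutation calling.

    ``mutations`` lists (site_index, sample) pairs carrying a homozygous
    non-parental allele.  Columns: sample, pos, n_parental, n_alt, depth,
    score.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    mut = {(s, i) for i, s in mutations}
    rows = []
    for sample in samples:
        depth = rng.poisson(coverage, size=n_sites)
        is_mut = np.array([(sample, i) in mut for i in range(n_sites)])
        p_alt = np.where(is_mut, 1 - error, error)
        n_alt = rng.binomial(depth, p_alt)
        rows.append(
            pd.DataFrame(
                {
                    "sample": sample,
                    "pos": np.arange(n_sites),
                    "n_parental": depth - n_alt,
                    "n_alt": n_alt,
                    "depth": depth,
                    "score": score,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# fixtures on disk


def write_fixture(outdir, genome, markers, counts, truth, sequences=None, tracks=None):
    """Write the cohort as plain-text files (TSV/BED/FASTA/JSON).

    Emitted positions are 1-based inclusive; the paired readers in
    :mod:`tetrada.io` restore the internal 0-based convention, so a write /
    read round-trip is lossless.
    """
    from tetrada import io as tio
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tio.write_marker_table(outdir / "markers.tsv", markers)
    tio.write_allele_counts(outdir / "allele_counts.tsv", counts)
    tio.write_genome_model(outdir, genome)
    tio.write_truth(outdir / "truth.json", truth)
    if sequences is not None:
        tio.write_fasta(outdir / "genome.fasta", sequences)
    if tracks is not None:
        for name, df in tracks.items():
            tio.write_bedgraph(outdir / f"{name}.bedgraph", df)
    return outdir
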