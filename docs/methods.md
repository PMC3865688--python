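# Methods

`tetrada` analyses meiotic recombination from per-marker allele counts of
recombinant offspring: complete tetrads (four products of one meiosis,
each carrying one recombinant haplotype from a Col/Ler-style F1 plus one
haplotype of a third "recipient" accession) and doubled-haploid (DH)
lines (fully homozygous single gametes).  This note describes the models,
the synthetic data they are validated on, the numerical choices, and the
limits of what the tests demonstrate.

## Genotyping and crossover calling

The observable at a marker is the pair of parental allele counts
(`n_P1`, `n_P2`) plus reads matching neither parent.  A marker is called
homozygous for the majority parent when its allele frequency reaches a
cutoff `c`, heterozygous when both parental alleles exceed `1 - c`, and
NOCALL below a minimum coverage or quality.  With a single cutoff these
two rules partition the callable space, so every sufficiently covered
marker receives a call.  For tetrad offspring the donor parent of the
recombinant haplotype follows from the call and the recipient allele: a
heterozygous call donates the parent the recipient does not match; a
homozygous call donates its own parent.  A homozygous call for the allele
the recipient does *not* carry is physically impossible in a diploid
sample and is flagged as a copy-number signature.

Crossovers are called by block merging: maximal runs of identical donor
assignments form blocks; runs of at least 25 consecutive markers are
seeds; a seed absorbs interspersed discordant runs until the nearest
opposite-genotype run with at least as many markers as the same-genotype
run immediately preceding it (ties stop the extension, conservatively;
chromosome-terminal sub-seed runs are absorbed into the adjacent seed so
no phantom terminal crossovers appear).  When the two extensions between
opposite seeds disagree, the left extension wins the contested runs and
the boundary is flagged.  This rule is deliberately simple, documented,
and verified against an independent reference implementation on random
call sequences; where several sub-seed runs alternate between two seeds
the behaviour is a design choice, not a claim about any published
implementation.

A crossover appears as a transition between adjacent opposite blocks. In
complete tetrads each crossover must appear reciprocally in exactly two
products, so transitions are paired across products by breakpoint-interval
overlap, greedily, largest overlap first.  A conversion tract at the
crossover shifts one product's observed transition by up to a tract
length, so reciprocal intervals can be disjoint; pairing therefore falls
back to the nearest opposite-direction partner within 25 kb.  The paired
event's breakpoint interval spans both products' transitions, which is
what guarantees it contains the true exchange point.  Transitions shared
by three or more products, and unpaired transitions, are flagged rather
than emitted: that pattern is the fingerprint of copy-number variation,
not of a double crossover.

Two crossovers closer than a seed width on the same product cannot be
separated by block merging (the intervening block is absorbed); such
pairs are recovered as one spanning event.  Recovery is therefore
measured as "every true exchange point lies inside a clean event's
breakpoint interval".

## The equal-error allele-frequency cutoff

Observed allele frequencies at homozygous-type markers cluster near 1,
at heterozygous-type markers near 0.5.  Beta distributions are fitted to
both (maximum likelihood, method-of-moments start; frequencies of exactly
0 or 1 are pulled inward by half a read, `1/(2*depth)`, before fitting).
The cutoff is the root of

    P_het(AF >= c) = P_hom(AF <= c)

found by bracketed bisection (brentq) to `|delta| < 1e-10`, so the two
genotype-misassignment rates are equal by construction.  Fits are made
per coverage stratum (bins of 10 reads, pooled above 100) because the
frequency variance shrinks with depth; a single global fit is available
where stratified counts are too thin.

Two caveats are deliberate.  First, the equal-error property holds for
the *fitted* distributions; the discrete error-read tail of real counts
is heavier than a beta fitted to the bulk, so the pipeline's default
operating point is the fixed cutoff 0.889 — the threshold at which the
two rules demand roughly six concordant error reads before miscalling at
50x, which is what drives the false-positive rate to zero on the study
conditions.  The fitted model is exposed (`cutoff="fit"`) and its
equal-error property is tested by Monte Carlo.  Second, the minimum
coverage is chosen from the data: the apparent conversion frequency
(converted / genotyped markers) is computed over a grid of coverage
thresholds and the plateau start — the smallest threshold beyond which
consecutive relative changes stay below a tolerance (default 10%) — is
the operating minimum.  Heterozygous samples plateau near 50x; homozygous
DH lines near 10x, because a missing allele is a far stronger signal at
equal depth.

## Conversion detection and the artifact-filter cascade

A non-crossover gene conversion (NCO-GC) is a confidently genotyped
marker that disagrees with its haplotype block: type-1 events turn an
expected homozygous genotype heterozygous (the expected allele equals
the recipient's), type-2 events the reverse.  Because the recipient
matches either parent with equal probability, the two types occur in
equal numbers; a type-1 excess indicates misaligned reads, not biology.
Discordant markers adjacent in the confident-marker sequence with no
intervening concordant call merge into one tract.  Markers inside paired
crossover breakpoint intervals are excluded (they belong to CO-associated
conversion); markers discordant in two or more products of one tetrad
violate 3:1 segregation and are flagged as artifacts.

CO-associated conversions (CO-GC) are the markers between the two
reciprocal transition points of a paired crossover at which the four
products segregate 3:1; all markers of a tract must convert in the same
direction (co-conversion), otherwise the event is flagged complex.
Events without four callable products over the span are marked
insufficient — with heterozygous samples at 50x this is the common case,
exactly as manual tract refinement was needed in practice.

The filter cascade mirrors the failure modes of short-read genotyping of
structurally divergent genomes.  Each filter is independent and its
provenance is recorded:

* `quality` — marker quality floor (default 24);
* `dup_te_2kb` — within 2 kb of an annotated duplication or transposon;
* `het_parent_1kb` — within 1 kb of a position where an inbred parent
  shows a second allele at >= 15% frequency (inbred parents are
  homozygous; apparent heterozygosity means misalignment);
* `init_150bp` — within 150 bp of any two-allele evidence (>= 2 reads)
  in a parent;
* `three_parent_reads` — within 300 bp (about a read-pair span) of a
  locus where one sample shows the recipient-specific allele *and* both
  parental alleles together: three haplotypes aligning where at most two
  chromosomes exist;
* `low_alignability` — below an alignability-fraction floor, when a
  track is supplied;
* `sanger_2to2` — an externally supplied blacklist of validation-rejected
  positions (wet-lab input; empty by default).

The count-table abstraction cannot re-align read pairs, so the
three-parent filter keys on recipient-informative sentinel sites —
positions where the recipient carries a third allele.  A normal sample
shows the recipient allele plus exactly one parental allele there; decoy
or CNV reads add the second parental allele and trip the filter.

## Rates

Conversion and mutation rates are ratios of converted markers (or
mutations) to confidently genotyped loci, the denominator being counted
per sample under the same coverage/cutoff/filter rules and logged so it
is auditable.  The spread is the between-meiosis variability from a
leave-one-meiosis-out jackknife when per-meiosis counts are available,
else the binomial standard error.  Spontaneous mutations in DH lines are
sites where exactly one line shows a confident homozygous non-parental
allele (score >= 32, coverage >= 10, frequency above the cutoff) and all
other lines confidently show the parental allele; variants in two or
more lines are inherited and excluded.

## Tract-length inference

Observed conversion tracts are far shorter than the marker spacing, so
length is inferred by simulation: 10,000 (configurable) sets of n tracts
of a fixed candidate length L are placed uniformly on the
non-peri-centromeric marker landscape (each tract kept inside one mask
interval, start uniform over the admissible positions), and the mean
total number of converted markers and the mean converted markers per
converting tract (tracts overlapping no marker are excluded from that
mean) are tabulated over a 100-1,000 bp grid.  Inverting the two curves
at the observed statistics gives two point estimates whose span is the
length interval; the curves are Monte-Carlo noisy, so they are
monotonized by cumulative maximum before linear interpolation, and an
observation outside the simulated range raises with the direction to
extend the grid.  The exact expectation
`E[total] = n * sum_m P(tract covers marker m)` is computed by discrete
enumeration over admissible starts and used as an oracle in the tests.
A length-distribution mode exists but fixed lengths are the default:
with marker spacing near 500 bp the data cannot distinguish a fixed
length from moderate length variation, and the interval between the two
statistics already absorbs that.

For NCO tracts the number of events is unknown, so scenarios are scanned
over a grid of DSB counts per meiosis, with a configurable fraction
(default one half) restored to the original allele and therefore
invisible; each scenario reports the same two statistics.  The
characteristic result — reproduced on synthetic maps — is that many
short tracts and few long tracts can convert the same total number of
markers, but long tracts co-convert more markers per tract, which is the
statistic that separates the hypotheses.

## Interference

The interference statistic is the mean distance between adjacent
same-tetrad events per chromosome (or, for CO-NCO, from each NCO to its
nearest same-tetrad CO); inter-chromosomal pairs are excluded.  The null
reassigns each event's tetrad label uniformly at random with positions
fixed, preserving the inhomogeneous placement of recombination along
chromosomes while destroying within-meiosis dependence.  One-sided
p-values use the add-one estimator `(1 + #{null >= obs}) / (n_iter + 1)`;
an exhaustive-enumeration mode replaces sampling for toy inputs and is
tested against independent brute force.  The iid-uniform reassignment is
the exact conditional null when per-tetrad events are Poisson processes
of equal rate (superposition), which is how the calibration fixtures are
generated (gamma shape 1, no obligate crossover).  With an obligate
crossover per chromosome the true label distribution is more even than
multinomial and the test becomes slightly anticonservative — a property
of the label-randomization design itself, worth remembering when event
counts per chromosome are near one.

The generator's inter-crossover spacing is a stationary gamma renewal
process (burn-in from ten mean spacings upstream); shape 1 is Poisson
placement, larger shapes produce the regular spacing characteristic of
interference and serve as positive controls.

## Genomic-context statistics

Recombination sites (conversion tracts plus 500 bp flanks, clipped at
chromosome ends) are compared against backgrounds sampled strictly from
the supplied mask (non-peri-centromeric arms): GC fraction (Welch t test
for means, median-centred Levene for spread), quantitative bedGraph
tracks such as methylation or MNase coverage (length-weighted interval
means; sites without track coverage are dropped and counted),
annotation categories (promoter = 500 bp upstream of the TSS,
strand-aware; gene end = last 200 bp; precedence promoter > gene end >
gene body > transposon > intergenic; null = equally many random mask
midpoints; two-sided add-one p), PWM motif rescreening (a region matches
when any window on either strand reaches the score whose exact tail
probability under the background base composition is below `match_p`,
computed by dynamic programming over an integer score grid at 1e-3
resolution), and nucleosome-exclusion distances (exact scans for
`A{10,}`/`T{10,}` and `[CG]{3}NN[CG]{3}NN[CG]{3}`; site-midpoint to
nearest-motif distances vs random midpoints, one-sided Mann-Whitney for
"closer").  Site midpoints of even-length intervals round down.

The default match threshold `match_p = 0.001` saturates on kilobase-scale
flanked regions (any-match probability approaches one on random
sequence); analyses that need discrimination on synthetic sequence use
`match_p = 1e-5`-`1e-6` or shorter flanks.  The shipped PWMs (poly-A and
GAA/CTT repeat) are consensus-derived stand-ins for externally discovered
motifs; motif discovery itself is out of scope.

## The synthetic cohort

The generator emulates the study design, not raw reads.  Defaults are
the study conditions: five deeply sequenced tetrads and ten DH lines on
a five-chromosome genome (5 Mb each here — full chromosome length adds
nothing the statistics see), 2e-3 markers/bp, ~10 crossovers per meiosis
(obligate crossover per chromosome), 62% of crossovers carrying a
conversion tract of 350 +/- 50 bp straddling the breakpoint (extent
split uniformly), 100 DSBs per meiosis minus realized crossovers as NCO
candidates with half restored, NCO tracts 37 +/- 12 bp, negative-binomial
depth at 60x (dispersion 0.1), 0.5% per-read error flipping a read to a
uniformly chosen other allele, and a recipient allele matching either
parent with probability one half.  Two percent of markers are
recipient-informative (third allele) — these are excluded from
genotyping and serve only the three-parent filter.

Crossovers are realized on the four-strand bivalent: each junction joins
one chromatid of each homolog, and the two products traversing those
strands at that position swap donor parent from there on, so every
crossover is a visible reciprocal transition and 2:2 segregation holds
outside conversion tracts by construction (a tested invariant).
Conversion tracts overwrite one product's paint inside the tract,
producing 3:1 segregation at covered markers.

Artifacts: `triple_haplotype` adds a constant fraction (default 1/3) of
decoy-haplotype reads to every sample in an interval; the decoy carries
P1/P2/novel alleles at 35/35/30%, which makes inbred parents look
heterozygous and creates exclusively type-1 false conversions — the
diagnostic asymmetry.  `transposition_cnv` gives each product a copy
number of the transposed interval computed from its haplotype at the
source locus and the insertion point; a crossover between them yields
one product with zero copies (only recipient reads: false type-2) and
its sibling with two (both parental alleles: false type-1).  Artifact
intervals carry densified sentinel sites (200 bp spacing), emulating the
local divergence of rearranged sequence that makes three-haplotype
evidence detectable in practice; without informative sites inside the
interval no count-level filter could see the rearrangement.

What the generator does not model: read-level artifacts (mapping
quality, base quality, indel realignment), linked-read haplotype
information, GC-biased coverage, biased gene conversion, EMS mutations
in the recipient, and genuine segmental duplications beyond the two
artifact classes.  Passing the recovery tests therefore shows the
*logic* of the pipeline is sound under the stated noise model; it does
not certify performance on real alignments, where the filter windows and
thresholds would need re-tuning against validation data.

All randomness flows from one integer seed through named substreams
(genome, meiosis, counts, ...), so each stage is independently
reproducible; every Monte-Carlo routine takes an explicit generator.

## Problem sizes

The bundled drivers and checks use: 5 tetrads x 5 chromosomes x 5 Mb at
2e-3 markers/bp (≈50,000 markers, ≈1.1 M count rows); tract grids of
100-1,000 bp at 1,000-2,000 replicates of 71 tracts; interference tests
at 2,000 iterations (199 for calibration sweeps over 60-100 fixtures);
context tests on 2 x 400-600 kb sequenced genomes with 25-40 sites and
backgrounds of 300-5,000 regions.  These sizes were chosen so every
statistic's Monte-Carlo error is small against the effects being
demonstrated while the whole analysis reruns in minutes.

## Known limitations

* Closely spaced double crossovers below the seed width merge into one
  spanning event (inherent to block merging at this marker density).
  Two rarer configurations are invisible outright: a double crossover
  whose two exchanges involve the *same* pair of products within a seed
  width (both transitions are absorbed in both products), and a
  crossover within a seed width of a chromosome end (the terminal block
  is absorbed).  Their leftover discordant markers appear as
  opposite-direction candidate tracts in two products and are flagged as
  a reciprocal pattern — conversion is non-reciprocal, so nearby
  opposite-direction candidates in one tetrad (within 10 kb by default)
  are a crossover signature, never emitted as conversions.
* CO-GC detection requires all four products callable at the tract
  markers; at 50x on heterozygous samples most true CO tracts are
  reported "insufficient data", so CO-GC fractions from the pipeline are
  a lower bound.
* The equal-error cutoff balances the two *beta-model* error rates; on
  discrete counts the operating point 0.889 is the validated default.
* The tetrad-label interference null is exact only without an obligate
  crossover; with one it is mildly anticonservative.
* Rate denominators count marker-loci, so rates are per assayable
  polymorphic site, not per genomic base.
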