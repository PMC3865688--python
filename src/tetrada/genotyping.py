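"""Genotype calling and crossover detection by seeded block merging.

A tetrad offspring carries one recombinant donor haplotype (P1/P2 mosaic)
and one recipient haplotype; the observable genotype at a marker is either
homozygous (donor allele equals the recipient's) or heterozygous.  The
donor-parent assignment per marker is reconstructed from the call plus the
marker's recipient allele, runs of identical donor assignments are merged
into blocks (seeds need ``seed_min_markers`` consecutive markers; seeds are
extended over interspersed discordant singletons until the nearest
opposite-genotype block with more markers than the preceding block), and
crossovers are the transitions between adjacent opposite blocks.  In
complete tetrads every crossover must appear reciprocally in exactly two
products.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# state / donor codes
P1, P2, HET, NOCALL = 0, 1, 2, -1

CALL_COLUMNS = ["sample", "chrom", "pos", "depth", "af_P1", "state", "donor", "inconsistent"]


def call_genotypes(
    counts: pd.DataFrame,
    markers: pd.DataFrame,
    cutoff,
    min_cov: int = 50,
    min_quality: int = 15,
    kind: str = "tetrad",
) -> pd.DataFrame:
    """Call per-marker genotypes from allele counts.

    ``cutoff`` is a :class:`~tetrada.af_model.CutoffModel` (or anything with
    ``cutoff_for(depth)``).  A marker is homozygous for the majority parent
    when its allele frequency reaches the coverage-dependent cutoff,
    heterozygous when both parental alleles exceed ``1 - cutoff`` (with a
    beta-derived cutoff these two rules partition the callable space), and
    NOCALL below ``min_cov`` / ``min_quality``.  For tetrad samples the
    ``donor`` column gives the inferred parent of the recombinant haplotype
    (HET calls donate the non-recipient allele); for DH samples the state is
    the donor and HET is uncallable.

    Raises if ``counts`` contains loci absent from ``markers``.
    """
    if kind not in ("tetrad", "dh"):
        raise ValueError("kind must be 'tetrad' or 'dh'")
    mk = markers[["chrom", "pos", "recipient_class", "quality", "triallelic"]]
    df = counts.merge(mk, on=["chrom", "pos"], how="left")
    if df["quality"].isna().any():
        missing = df[df["quality"].isna()][["chrom", "pos"]].drop_duplicates()
        raise ValueError(
            f"{len(missing)} count loci absent from the marker table "
            f"(first: {missing.iloc[0].tolist()})"
        )

    depth = (df["n_P1"] + df["n_P2"]).to_numpy(dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        af1 = np.where(depth > 0, df["n_P1"].to_numpy() / np.maximum(depth, 1), np.nan)
    c = cutoff.cutoff_for(depth)

    state = np.full(len(df), HET, dtype=np.int8)
    state[af1 >= c] = P1
    state[(1.0 - af1) >= c] = P2
    uncallable = (
        (depth < min_cov)
        | (df["quality"].to_numpy() < min_quality)
        | df["triallelic"].to_numpy()
    )
    state[uncallable] = NOCALL

    recipient = df["recipient_class"].to_numpy()
    donor = np.full(len(df), NOCALL, dtype=np.int8)
    inconsistent = np.zeros(len(df), dtype=bool)
    if kind == "tetrad":
        hom = (state == P1) | (state == P2)
        donor[hom] = state[hom]
        het = state == HET
        donor[het] = (1 - recipient[het]).astype(np.int8)
        # homozygous for the allele the recipient does NOT carry: the
        # recipient haplotype went missing -- a copy-number signature
        inconsistent = hom & (recipient != state) & (recipient <= 1)
    else:
        hom = (state == P1) | (state == P2)
        donor[hom] = state[hom]

    out = pd.DataFrame(
        {
            "sample": df["sample"],
            "chrom": df["chrom"],
            "pos": df["pos"],
            "depth": depth,
            "af_P1": af1,
            "state": state,
            "donor": donor,
            "inconsistent": inconsistent,
        }
    )
    return out.sort_values(["sample", "chrom", "pos"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# block merging


def _runs(values: np.ndarray):
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    return starts, ends


def merge_runs(run_states: np.ndarray, run_lens: np.ndarray, seed_min: int):
    """Assign each run to a merged super-block (the documented seed rule).

    Returns an array mapping run index -> block id, or None when no run
    reaches ``seed_min`` markers (the chromosome is un-genotypable).
    Extension from a seed stops at the nearest opposite-genotype run with at
    least as many markers as the same-genotype run immediately preceding it
    (ties stop, conservatively); chromosome-terminal runs are absorbed into
    the adjacent seed's extension.
    """
    nr = len(run_states)
    seeds = np.flatnonzero(run_lens >= seed_min)
    if len(seeds) == 0:
        return None
    block = np.full(nr, -1, dtype=int)
    bid = 0
    block[: seeds[0] + 1] = bid  # leading runs absorb into the first seed
    for sa, sb in zip(seeds[:-1], seeds[1:]):
        if run_states[sa] == run_states[sb]:
            block[sa : sb + 1] = bid  # same genotype: one super-block
            continue
        # extend sa rightward
        ra = sa
        k = sa + 1
        while k < sb:
            if run_states[k] != run_states[sa] and run_lens[k] >= run_lens[k - 1]:
                break
            if run_states[k] == run_states[sa]:
                ra = k
            k += 1
        # extend sb leftward
        rb = sb
        k = sb - 1
        while k > sa:
            if run_states[k] != run_states[sb] and run_lens[k] >= run_lens[k + 1]:
                break
            if run_states[k] == run_states[sb]:
                rb = k
            k -= 1
        if rb <= ra:  # both extensions claim the middle; left wins the tie
            rb = ra + 1
        block[sa : ra + 1] = bid
        bid += 1
        block[rb : sb + 1] = bid
        # leftover runs between the two extensions join the right block
        block[ra + 1 : rb] = bid
    block[seeds[-1] :] = bid  # trailing runs absorb into the last seed
    return block


def merge_blocks(calls: pd.DataFrame, seed_min_markers: int = 25):
    """Merge confident donor calls into genotype blocks per sample/chromosome.

    Returns ``(blocks, candidates, seedless)``: the merged blocks (state =
    majority donor of the super-block), the interspersed discordant markers
    recorded as conversion candidates, and the (sample, chrom) combinations
    with no seed at all.
    """
    conf = calls[calls["donor"] >= 0]
    blocks_rows, cand_rows, seedless = [], [], []
    for (sample, chrom), grp in conf.groupby(["sample", "chrom"], sort=True):
        donor = grp["donor"].to_numpy()
        pos = grp["pos"].to_numpy()
        if len(donor) == 0:
            seedless.append((sample, chrom))
            continue
        starts, ends = _runs(donor)
        run_states = donor[starts]
        run_lens = ends - starts
        block = merge_runs(run_states, run_lens, seed_min_markers)
        if block is None:
            seedless.append((sample, chrom))
            continue
        for bid in range(block.max() + 1):
            runs_in = np.flatnonzero(block == bid)
            seed_state = run_states[runs_in[np.argmax(run_lens[runs_in])]]
            first, last = starts[runs_in[0]], ends[runs_in[-1]] - 1
            concord = sum(
                run_lens[k] for k in runs_in if run_states[k] == seed_state
            )
            blocks_rows.append(
                (sample, chrom, bid, seed_state, pos[first], pos[last], concord,
                 int(ends[runs_in[-1]] - starts[runs_in[0]]))
            )
            for k in runs_in:
                if run_states[k] != seed_state:
                    for i in range(starts[k], ends[k]):
                        cand_rows.append(
                            (sample, chrom, pos[i], int(donor[i]), int(seed_state))
                        )
    blocks = pd.DataFrame(
        blocks_rows,
        columns=["sample", "chrom", "block", "state", "start_pos", "end_pos",
                 "n_markers", "n_total"],
    )
    candidates = pd.DataFrame(
        cand_rows, columns=["sample", "chrom", "pos", "donor", "block_state"]
    )
    seedless = pd.DataFrame(seedless, columns=["sample", "chrom"])
    return blocks, candidates, seedless


# ---------------------------------------------------------------------------
# crossovers


def _transitions(blocks: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (sample, chrom), grp in blocks.groupby(["sample", "chrom"], sort=True):
        grp = grp.sort_values("block")
        for left, right in zip(grp.itertuples(), list(grp.itertuples())[1:]):
            rows.append(
                (sample, chrom, left.end_pos, right.start_pos,
                 int(left.state), int(right.state))
            )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "left_pos", "right_pos", "from_state", "to_state"]
    )


def detect_crossovers(
    blocks: pd.DataFrame,
    tetrads: dict[str, str] | None = None,
    max_pair_gap: int = 25_000,
) -> pd.DataFrame:
    """Turn block transitions into crossover events.

    ``tetrads`` maps sample name -> meiosis name for tetrad products;
    samples absent from the map are treated as DH lines (their transitions
    are events directly).  Tetrad transitions are paired across products by
    breakpoint-interval overlap (greedy, largest overlap first), falling
    back to the nearest non-overlapping partner within ``max_pair_gap`` --
    a conversion tract at the crossover shifts one product's transition, so
    reciprocal intervals need not overlap.  The paired event's breakpoint
    interval spans both products' transitions.  Unpaired transitions and
    breakpoints shared by more than two products are flagged, not emitted as
    clean events.
    """
    tetrads = tetrads or {}
    trans = _transitions(blocks)
    rows = []
    dh_trans = trans[~trans["sample"].isin(tetrads)]
    for t in dh_trans.itertuples():
        rows.append(
            (t.sample, t.chrom, t.left_pos, t.right_pos, (t.sample,), False, "")
        )
    tt = trans[trans["sample"].isin(tetrads)].copy()
    if len(tt):
        tt["meiosis"] = tt["sample"].map(tetrads)
        for (meiosis, chrom), grp in tt.groupby(["meiosis", "chrom"], sort=True):
            recs = list(grp.itertuples())
            pairs = []
            for i in range(len(recs)):
                for j in range(i + 1, len(recs)):
                    a, b = recs[i], recs[j]
                    if a.sample == b.sample:
                        continue
                    if (a.from_state, a.to_state) != (b.to_state, b.from_state):
                        continue  # reciprocal exchange runs the other way
                    overlap = min(a.right_pos, b.right_pos) - max(a.left_pos, b.left_pos)
                    if overlap >= 0 or -overlap <= max_pair_gap:
                        pairs.append((overlap, i, j))
            pairs.sort(key=lambda x: -x[0])
            used = set()
            paired = {}
            for overlap, i, j in pairs:
                if i in used or j in used:
                    continue
                used.update((i, j))
                paired[i] = (j, overlap)
            matched_regions = []
            for i, (j, overlap) in paired.items():
                a, b = recs[i], recs[j]
                left = min(a.left_pos, b.left_pos)
                right = max(a.right_pos, b.right_pos)
                co_gc = (a.left_pos, a.right_pos) != (b.left_pos, b.right_pos)
                rows.append(
                    (meiosis, chrom, left, right, (a.sample, b.sample), co_gc, "")
                )
                matched_regions.append((left, right, len(rows) - 1))
            for i, t in enumerate(recs):
                if i in used:
                    continue
                flag = "unpaired"
                for left, right, ridx in matched_regions:
                    if t.left_pos <= right and t.right_pos >= left:
                        flag = "multi_product"
                        rows[ridx] = rows[ridx][:6] + ("multi_product",)
                rows.append(
                    (meiosis, chrom, t.left_pos, t.right_pos, (t.sample,), False, flag)
                )
    events = pd.DataFrame(
        rows,
        columns=["meiosis", "chrom", "left_pos", "right_pos", "products",
                 "co_gc_associated", "flag"],
    )
    if len(events):
        bad = events["right_pos"] - events["left_pos"] < 1
        events.loc[bad, "flag"] = (events.loc[bad, "flag"] + ";zero_width").str.lstrip(";")
    return events.sort_values(["meiosis", "chrom", "left_pos"]).reset_index(drop=True)


def summarize_co(events: pd.DataFrame, n_meioses: int) -> dict:
    """Per-meiosis and per-chromosome crossover statistics.

    Flagged events are excluded from the clean totals.
    """
    if n_meioses < 1:
        raise ValueError("need at least one meiosis")
    clean = events[events["flag"] == ""] if len(events) else events
    per_chrom = (
        clean.groupby("chrom").size().to_dict() if len(clean) else {}
    )
    per_meiosis = (
        clean.groupby("meiosis").size().to_dict() if len(clean) else {}
    )
    return {
        "n_events": int(len(clean)),
        "n_flagged": int(len(events) - len(clean)),
        "n_meioses": int(n_meioses),
        "mean_per_meiosis": len(clean) / n_meioses,
        "per_chrom": per_chrom,
        "per_meiosis": per_meiosis,
    }
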