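"""Genotype calls, block merging and crossover pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tetrada.af_model import CutoffModel
from tetrada.genotyping import (
    HET,
    NOCALL,
    P1,
    P2,
    call_genotypes,
    detect_crossovers,
    merge_blocks,
    merge_runs,
    summarize_co,
)
from tetrada.pipeline import analyze_tetrads, co_recovery, tetrad_sample_map


def _mk(n=1, recipient_class=0):
    return pd.DataFrame(
        {
            "chrom": "c1",
            "pos": np.arange(n) * 100,
            "allele_P1": "A",
            "allele_P2": "G",
            "allele_recipient": "A" if recipient_class == 0 else "G",
            "recipient_class": np.int8(recipient_class),
            "quality": 40,
            "triallelic": False,
            "decoy": np.int8(-1),
        }
    )


def _counts(n_p1, n_p2, pos=0):
    return pd.DataFrame(
        {
            "sample": ["s1"],
            "chrom": ["c1"],
            "pos": [pos],
            "n_P1": [n_p1],
            "n_P2": [n_p2],
            "n_other": [0],
            "depth": [n_p1 + n_p2],
        }
    )


@pytest.mark.parametrize(
    "n_p1,n_p2,min_cov,expected_state",
    [
        (48, 2, 10, P1),     # frequency 0.96 >= 0.889 -> homozygous
        (5, 4, 10, NOCALL),  # depth 9 below the coverage floor
        (26, 24, 10, HET),   # 0.52/0.48: both alleles above 1 - 0.889
        (2, 48, 10, P2),
    ],
)
def test_call_rule(n_p1, n_p2, min_cov, expected_state):
    calls = call_genotypes(
        _counts(n_p1, n_p2), _mk(), CutoffModel.fixed(0.889), min_cov=min_cov
    )
    assert calls["state"].iloc[0] == expected_state


def test_het_call_donates_non_recipient_parent():
    calls = call_genotypes(_counts(26, 24), _mk(recipient_class=0),
                           CutoffModel.fixed(0.889), min_cov=10)
    assert calls["donor"].iloc[0] == P2
    calls = call_genotypes(_counts(26, 24), _mk(recipient_class=1),
                           CutoffModel.fixed(0.889), min_cov=10)
    assert calls["donor"].iloc[0] == P1


def test_unknown_locus_raises():
    with pytest.raises(ValueError, match="absent"):
        call_genotypes(_counts(10, 10, pos=12345), _mk(), CutoffModel.fixed(0.889))


def _calls_from_donor_sequence(donor):
    n = len(donor)
    return pd.DataFrame(
        {
            "sample": "s1",
            "chrom": "c1",
            "pos": np.arange(n) * 100,
            "depth": 50,
            "af_P1": 1.0,
            "state": np.asarray(donor, dtype=np.int8),
            "donor": np.asarray(donor, dtype=np.int8),
            "inconsistent": False,
        }
    )


def test_merge_blocks_worked_example():
    """30xP1, 1xP2, 30xP1, 40xP2 with seed 25: two blocks, breakpoint
    between the 61st and 62nd markers, the singleton P2 kept as candidate."""
    donor = [0] * 30 + [1] + [0] * 30 + [1] * 40
    blocks, cand, seedless = merge_blocks(_calls_from_donor_sequence(donor))
    assert len(blocks) == 2 and len(seedless) == 0
    left, right = blocks.iloc[0], blocks.iloc[1]
    assert left["state"] == P1 and left["n_markers"] == 60 and left["n_total"] == 61
    assert right["state"] == P2 and right["n_markers"] == 40
    assert left["end_pos"] == 60 * 100  # 61st marker (0-based index 60)
    assert right["start_pos"] == 61 * 100
    assert len(cand) == 1 and cand.iloc[0]["pos"] == 30 * 100


def test_merge_blocks_single_state():
    blocks, cand, _ = merge_blocks(_calls_from_donor_sequence([1] * 50))
    assert len(blocks) == 1 and len(cand) == 0


def test_merge_blocks_no_seed_flags_chromosome():
    donor = [0] * 24 + [1] * 24
    blocks, _, seedless = merge_blocks(_calls_from_donor_sequence(donor))
    assert len(blocks) == 0
    assert seedless.iloc[0].tolist() == ["s1", "c1"]


def _reference_merge(states, seed_min):
    """Independent, deliberately-naive implementation of the merging rule."""
    runs = [(k, len(list(g))) for k, g in itertools.groupby(states)]
    seeds = [i for i, (_, n) in enumerate(runs) if n >= seed_min]
    if not seeds:
        return None
    assign = [-1] * len(runs)
    for i in range(seeds[0] + 1):
        assign[i] = 0
    bid = 0
    for sa, sb in zip(seeds, seeds[1:]):
        if runs[sa][0] == runs[sb][0]:
            for i in range(sa, sb + 1):
                assign[i] = bid
            continue
        ra = sa
        k = sa + 1
        while k < sb:
            if runs[k][0] != runs[sa][0] and runs[k][1] >= runs[k - 1][1]:
                break
            if runs[k][0] == runs[sa][0]:
                ra = k
            k += 1
        rb = sb
        k = sb - 1
        while k > sa:
            if runs[k][0] != runs[sb][0] and runs[k][1] >= runs[k + 1][1]:
                break
            if runs[k][0] == runs[sb][0]:
                rb = k
            k -= 1
        if rb <= ra:
            rb = ra + 1
        for i in range(sa, ra + 1):
            assign[i] = bid
        bid += 1
        for i in range(ra + 1, sb + 1):
            assign[i] = bid
    for i in range(seeds[-1], len(runs)):
        assign[i] = bid
    return assign


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(0, 1), min_size=1, max_size=200),
    st.integers(2, 30),
)
def test_merge_rule_matches_reference(states, seed_min):
    states_arr = np.asarray(states, dtype=np.int8)
    change = np.flatnonzero(np.diff(states_arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(states_arr)]])
    got = merge_runs(states_arr[starts], ends - starts, seed_min)
    want = _reference_merge(states, seed_min)
    if want is None:
        assert got is None
    else:
        assert got is not None and got.tolist() == want


def test_dh_transitions_become_events():
    donor = [0] * 30 + [1] * 30 + [0] * 30 + [1] * 30 + [0] * 30 + [1] * 30 + [0] * 30
    blocks, _, _ = merge_blocks(_calls_from_donor_sequence(donor))
    events = detect_crossovers(blocks)
    assert len(events) == 6
    assert (events["flag"] == "").all()


def test_tetrad_reciprocity_and_recovery(study_cohort):
    """On artifact-free tetrads every clean CO pairs two products and the
    breakpoint interval contains the true position."""
    _, genome, markers, truth, counts = study_cohort
    res = analyze_tetrads(markers, counts, genome, tetrad_sample_map(truth))
    clean = res.co_events[res.co_events["flag"] == ""]
    assert (clean["products"].apply(len) == 2).all()
    rec = co_recovery(truth, res.co_events)
    assert rec["recovery"] == 1.0


def test_summarize_co_statistics():
    ev = pd.DataFrame(
        {
            "meiosis": ["m1"] * 131,
            "chrom": "c1",
            "left_pos": 0,
            "right_pos": 1,
            "products": [("a", "b")] * 131,
            "co_gc_associated": False,
            "flag": "",
        }
    )
    s = summarize_co(ev, n_meioses=13)
    assert round(s["mean_per_meiosis"], 1) == 10.1
    assert summarize_co(ev.iloc[0:0], n_meioses=5)["mean_per_meiosis"] == 0
    s2 = summarize_co(ev.iloc[:60], n_meioses=10)
    assert s2["mean_per_meiosis"] == 6.0
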