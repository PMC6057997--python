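"""Phasing: linkage counting, block construction, merging, extraction.

The reference point for phase_locus is an exhaustive oracle that scores
every possible orientation assignment by summed concordant fragment
co-observations and returns the maximum.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonelineage import simulate
from clonelineage.formats import AlignedRead
from clonelineage.phasing import (
    build_cooccurrence,
    extract_alleles,
    merge_blocks,
    phase_locus,
)
from clonelineage.variants import HetSite


def _fragment(pair_id, observations, locus="loc"):
    """Reads (possibly one per site) all sharing one pair id."""
    reads = []
    for k, (pos, base) in enumerate(observations):
        reads.append(
            AlignedRead(
                read_id=f"{pair_id}/{k}", pair_id=pair_id, locus_id=locus,
                start=pos, sequence=base,
                qualities=np.array([35], dtype=np.uint8), cigar=[("M", 1)],
                is_read1=(k == 0),
            )
        )
    return reads


def _sites(alleles, spacing=10):
    return [
        HetSite("loc", i * spacing, a, b, 10, 10) for i, (a, b) in enumerate(alleles)
    ]


def brute_force_phase(sites, cooc):
    """Maximize summed concordant co-observations over all orientations."""
    n = len(sites)
    best_score, best = -1, None
    for assignment in itertools.product((0, 1), repeat=n):
        score = 0
        for (i, j), counter in cooc.pair_counts.items():
            for (bi, bj), count in counter.items():
                hap_i = (sites[i].base1, sites[i].base2)[assignment[i]]
                hap_j = (sites[j].base1, sites[j].base2)[assignment[j]]
                alt_i = (sites[i].base2, sites[i].base1)[assignment[i]]
                alt_j = (sites[j].base2, sites[j].base1)[assignment[j]]
                if (bi, bj) in ((hap_i, hap_j), (alt_i, alt_j)):
                    score += count
        if score > best_score:
            best_score, best = score, assignment
    return best, best_score


def _block_score(blocks, sites, cooc):
    pos_to_idx = {s.position: k for k, s in enumerate(sites)}
    assignment = {}
    for blk in blocks:
        for pos, a in zip(blk.positions, blk.hap_a):
            k = pos_to_idx[pos]
            assignment[k] = 0 if a == sites[k].base1 else 1
    score = 0
    for (i, j), counter in cooc.pair_counts.items():
        for (bi, bj), count in counter.items():
            hap_i = (sites[i].base1, sites[i].base2)[assignment[i]]
            hap_j = (sites[j].base1, sites[j].base2)[assignment[j]]
            alt_i = (sites[i].base2, sites[i].base1)[assignment[i]]
            alt_j = (sites[j].base2, sites[j].base1)[assignment[j]]
            if (bi, bj) in ((hap_i, hap_j), (alt_i, alt_j)):
                score += count
    return score


def test_no_shared_fragment_gives_empty_matrix():
    sites = _sites([("A", "C"), ("G", "T")], spacing=100)
    reads = _fragment("f1", [(0, "A")]) + _fragment("f2", [(100, "G")])
    cooc = build_cooccurrence(sites, reads)
    assert cooc.pair_counts == {}


def test_cis_fragments_counted():
    sites = _sites([("A", "G"), ("C", "T")])
    reads = []
    for k in range(10):
        base_pair = [(0, "A"), (10, "C")] if k % 2 == 0 else [(0, "G"), (10, "T")]
        reads += _fragment(f"f{k}", base_pair)
    cooc = build_cooccurrence(sites, reads)
    assert cooc.cis_trans(0, 1) == (10, 0)


def test_third_base_is_noise_not_linkage():
    sites = _sites([("A", "G"), ("C", "T")])
    reads = _fragment("f1", [(0, "A"), (10, "C")]) + _fragment("f2", [(0, "T"), (10, "C")])
    cooc = build_cooccurrence(sites, reads)
    assert cooc.cis_trans(0, 1) == (1, 0)


def test_single_site_singleton_block():
    sites = _sites([("A", "C")])
    cooc = build_cooccurrence(sites, [])
    blocks = phase_locus(sites, cooc)
    assert len(blocks) == 1
    assert {blocks[0].hap_a, blocks[0].hap_b} == {"A", "C"}


def test_three_site_chain_matches_exhaustive_oracle():
    sites = _sites([("A", "G"), ("C", "T"), ("A", "T")])
    reads = []
    for k in range(5):
        reads += _fragment(f"x{k}", [(0, "A"), (10, "C")])
        reads += _fragment(f"y{k}", [(10, "T"), (20, "A")])
    cooc = build_cooccurrence(sites, reads)
    blocks = phase_locus(sites, cooc)
    assert len(blocks) == 1
    oracle_assignment, oracle_score = brute_force_phase(sites, cooc)
    assert _block_score(blocks, sites, cooc) == oracle_score


@settings(max_examples=25, deadline=None)
@given(st.data())
def test_phase_matches_brute_force_on_error_free_fragments(data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    n = data.draw(st.integers(2, 8))
    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    sites = _sites([pairs[rng.integers(4)] for _ in range(n)])
    truth = rng.integers(0, 2, n)
    reads = []
    for f in range(data.draw(st.integers(1, 20))):
        lo = int(rng.integers(0, n))
        hi = int(rng.integers(lo, n))
        hap = int(rng.integers(2))
        obs = []
        for k in range(lo, hi + 1):
            base = (sites[k].base1, sites[k].base2)[truth[k] ^ hap]
            obs.append((sites[k].position, base))
        reads += _fragment(f"f{f}", obs)
    cooc = build_cooccurrence(sites, reads)
    blocks = phase_locus(sites, cooc)
    # partition property
    all_pos = sorted(p for b in blocks for p in b.positions)
    assert all_pos == [s.position for s in sites]
    # optimality property
    _, oracle_score = brute_force_phase(sites, cooc)
    assert _block_score(blocks, sites, cooc) == oracle_score


def test_merge_single_block_unchanged():
    sites = _sites([("A", "C")])
    blocks = phase_locus(sites, build_cooccurrence(sites, []))
    merged, rej = merge_blocks(blocks, [])
    assert merged == blocks and rej == []


def test_merge_bridges_two_blocks():
    sites = _sites([("A", "G"), ("C", "T")], spacing=500)
    cooc = build_cooccurrence(sites, [])
    blocks = phase_locus(sites, cooc)
    assert len(blocks) == 2
    bridge = _fragment("g1", [(0, "A"), (500, "T")])
    merged, rej = merge_blocks(blocks, bridge)
    assert len(merged) == 1 and rej == []
    idx = merged[0].positions.index(0)
    jdx = merged[0].positions.index(500)
    assert {merged[0].hap_a[idx] + merged[0].hap_a[jdx],
            merged[0].hap_b[idx] + merged[0].hap_b[jdx]} == {"AT", "GC"}


def test_contradictory_linkage_rejects_merge():
    sites = _sites([("A", "G"), ("C", "T")], spacing=500)
    blocks = phase_locus(sites, build_cooccurrence(sites, []))
    conflicting = (
        _fragment("g1", [(0, "A"), (500, "C")])
        + _fragment("g2", [(0, "A"), (500, "C")])
        + _fragment("g3", [(0, "A"), (500, "T")])
        + _fragment("g4", [(0, "A"), (500, "T")])
    )
    merged, rej = merge_blocks(blocks, conflicting)
    assert len(merged) == 2 and len(rej) == 1
    assert rej[0]["reason"] == "contradictory linkage"


def test_extract_alleles():
    sites = [HetSite("loc", 1, "C", "T", 10, 10)]
    blocks = phase_locus(sites, build_cooccurrence(sites, []))
    blk = blocks[0]
    a1, a2 = extract_alleles(blk, "ACGT")
    assert {a1, a2} == {"ACGT", "ATGT"}
    empty_blockless = extract_alleles(
        type(blk)(block_id="b", locus_id="loc", positions=[], hap_a="", hap_b=""),
        "ACGT",
    )
    assert empty_blockless == ("ACGT", "ACGT")


def test_preset_linkage_respects_planted_gaps(preset):
    """Adjacent het sites within a non-gap run are linked by some fragment;
    pairs flanking a planted gap are never linked, by either read set."""
    rna, gen = simulate.simulate_preset_reads(preset, "A", seed=2)
    checked_gaps = 0
    for t in preset.truth.loci[:12]:
        hets = [
            HetSite(t.locus_id, p, *sorted({t.haps_a[0][p], t.haps_a[1][p]}), 0, 0)
            for p in t.het_positions_a
        ]
        reads = [r for r in rna + gen if r.locus_id == t.locus_id]
        cooc = build_cooccurrence(hets, reads)
        for i in range(len(hets) - 1):
            cis, trans = cooc.cis_trans(i, i + 1)
            spans_gap = any(
                hets[i].position < g < hets[i + 1].position for g in t.gap_positions
            )
            if spans_gap:
                checked_gaps += 1
                assert cis + trans == 0
            else:
                assert cis + trans >= 1
    assert checked_gaps >= 2


def test_preset_block_count_merges_to_truth(preset, preset_report):
    assert preset_report["blocks_rna_only"] > 37
    assert preset_report["block_total"] == preset.truth.total_expected_blocks == 37
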