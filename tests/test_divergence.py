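"""NG86 counting against exhaustive and independent oracles; chaining rules."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonelineage import simulate
from clonelineage.divergence import (
    CODON_TO_AA,
    SENSE_CODONS,
    STOP_CODONS,
    GenePairAnchor,
    bin_log_ratios,
    chain_collinear,
    codon_syn_sites,
    filter_estimates,
    ng86_pair,
    summarize_divergence,
)

BASES = "ACGT"


def test_identical_sequences_flagged_zero():
    e = ng86_pair("ATGGCTAAA", "ATGGCTAAA")
    assert e.Sd == e.Nd == 0
    assert e.flags == {"ds_zero", "dn_zero"}
    assert not e.ok


def test_hand_counted_glu_codon_example():
    # GAA has one synonymous single-base change (GAA->GAG) out of nine, so
    # 1/3 synonymous site per codon; one such difference in ten codons gives
    # pS = 0.3 and dS = -0.75 ln(0.6).
    e = ng86_pair("GAA" * 10, "GAA" * 9 + "GAG")
    assert e.S == pytest.approx(10 / 3)
    assert (e.Sd, e.Nd) == (1.0, 0.0)
    assert e.pS == pytest.approx(0.30)
    assert e.dS == pytest.approx(-0.75 * math.log(0.6))


def test_site_counts_conserve_three_per_codon():
    rng = np.random.default_rng(0)
    for _ in range(20):
        codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=30)]
        e = ng86_pair("".join(codons), "".join(codons))
        assert e.S + e.N == pytest.approx(3 * 30)


def test_every_single_step_codon_change_matches_translation_oracle():
    """Exhaustive: for each sense codon and each single-base change to a
    sense codon, NG86 assigns the difference to the class the genetic code
    dictates, with Sd + Nd = 1."""
    for codon in SENSE_CODONS:
        for pos, base in itertools.product(range(3), BASES):
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt == codon or alt in STOP_CODONS:
                continue
            e = ng86_pair(codon, alt)
            assert e.Sd + e.Nd == pytest.approx(1.0)
            if CODON_TO_AA[codon] == CODON_TO_AA[alt]:
                assert (e.Sd, e.Nd) == (1.0, 0.0)
            else:
                assert (e.Sd, e.Nd) == (0.0, 1.0)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_estimator_is_symmetric(seed):
    pairs, _ = simulate.simulate_divergent_pairs(1, 50, 0.05, 0.6, seed=seed)
    a, b = pairs[0]
    e1, e2 = ng86_pair(a, b), ng86_pair(b, a)
    assert (e1.S, e1.N, e1.Sd, e1.Nd) == (e2.S, e2.N, e2.Sd, e2.Nd)


def test_matches_independent_library_implementation():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
    pairs, _ = simulate.simulate_divergent_pairs(5, 120, 0.05, 0.5, seed=21)
    for a, b in pairs:
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        e = ng86_pair(a, b)
        assert e.dS == pytest.approx(ds, abs=1e-4)
        assert e.dN == pytest.approx(dn, abs=1e-4)


def test_precondition_errors():
    with pytest.raises(ValueError):
        ng86_pair("ATG", "ATGA")
    with pytest.raises(ValueError):
        ng86_pair("ATGA", "ATGA")
    with pytest.raises(ValueError, match="internal stop"):
        ng86_pair("TAAGCT", "TAAGCT")


def test_codons_with_n_are_skipped():
    e = ng86_pair("ATGNNNGAA", "ATGNNNGAG")
    assert e.n_codons == 2 and e.Sd == 1.0


def test_filters_drop_zero_and_saturated():
    identical = ng86_pair("GAAGCT", "GAAGCT")
    ok_pairs, _ = simulate.simulate_divergent_pairs(3, 200, 0.05, 0.5, seed=2)
    ok = [ng86_pair(a, b) for a, b in ok_pairs]
    kept = filter_estimates([identical] + ok)
    assert len(kept) == sum(e.ok for e in ok)
    saturated = ng86_pair("GAA" * 10, "GAA" * 9 + "GAG")
    saturated.dS = 2.0  # forced saturation level
    saturated.flags = {"saturated"}
    assert filter_estimates([saturated]) == []


def test_saturation_flag_set_by_estimator():
    # maximally divergent codons drive p toward/above 3/4
    a = "TTT" * 40
    b = "GGG" * 40
    e = ng86_pair(a, b)
    assert "saturated" in e.flags and e.omega is None


def test_summaries_and_histogram():
    pairs, _ = simulate.simulate_divergent_pairs(300, 300, 0.024, 0.37, seed=8)
    kept = filter_estimates([ng86_pair(a, b) for a, b in pairs])
    s = summarize_divergence(kept)
    assert s["mean_dS"] == pytest.approx(0.024, rel=0.10)
    assert s["mean_omega"] == pytest.approx(0.37, rel=0.10)
    assert s["ratio_of_means"] == pytest.approx(0.37, rel=0.10)
    counts, edges = bin_log_ratios(kept, n_bins=60)
    assert counts.sum() == len(kept)
    assert len(counts) == 60
    mode_bin = int(np.argmax(counts))
    target = math.log10(0.37)
    assert edges[mode_bin] <= target <= edges[mode_bin + 1] or \
        abs(0.5 * (edges[mode_bin] + edges[mode_bin + 1]) - target) < 0.2
    with pytest.raises(ValueError):
        summarize_divergence([])


def test_mixture_recovers_high_omega_count():
    rng = np.random.default_rng(3)
    low, _ = simulate.simulate_divergent_pairs(190, 300, 0.024, 0.37, rng=rng)
    high, _ = simulate.simulate_divergent_pairs(10, 300, 0.024, 2.0, rng=rng)
    kept = filter_estimates([ng86_pair(a, b) for a, b in low + high])
    s = summarize_divergence(kept, threshold=1.5)
    assert 5 <= s["n_above"] <= 15


def _anchors(pairs, scaf=("s", "t")):
    return [
        GenePairAnchor(f"p{k}", scaf[0], ia, scaf[1], ib)
        for k, (ia, ib) in enumerate(pairs)
    ]


def test_chain_identical_order():
    chains = chain_collinear(_anchors([(i, i) for i in range(10)]))
    assert len(chains) == 1 and len(chains[0]) == 10


def test_four_anchors_below_minimum():
    assert chain_collinear(_anchors([(i, i) for i in range(4)])) == []


def test_gap_over_twenty_intervening_genes_splits():
    pairs = [(i, i if i < 3 else i + 21) for i in range(6)]
    assert chain_collinear(_anchors(pairs)) == []
    # exactly 20 intervening genes is allowed
    pairs_ok = [(i, i if i < 3 else i + 20) for i in range(6)]
    chains = chain_collinear(_anchors(pairs_ok))
    assert len(chains) == 1 and len(chains[0]) == 6


def test_inverted_chain_detected():
    chains = chain_collinear(_anchors([(i, 99 - i) for i in range(7)]))
    assert len(chains) == 1 and chains[0].orientation == "inverted"


def test_tandem_duplicates_condensed_before_chaining():
    pairs = [(0, 0), (1, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6)]
    chains = chain_collinear(_anchors(pairs))
    assert len(chains) == 1
    index_a = [a.index_a for a in chains[0].anchors]
    assert len(index_a) == len(set(index_a))
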