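"""Simulator truth: genealogy expectations, preset bookkeeping, read draws."""

import numpy as np
import pytest
from scipy import stats

from clonelineage import simulate
from clonelineage.simulate import (
    DiploidLocus,
    GenealogyModel,
    sharing_class_from_haplotypes,
    simulate_ancestry,
    simulate_genome_background,
    simulate_reads,
)
from clonelineage.variants import pileup
from clonelineage.formats import SequenceRecord


def test_model_validation():
    with pytest.raises(ValueError):
        GenealogyModel(hypothesis="cousins")
    with pytest.raises(ValueError):
        GenealogyModel(ancestral_het_rate=1.5)
    with pytest.raises(ValueError):
        GenealogyModel(n_loci=2, locus_lengths=[100, 101])  # not codon-sized


def test_parent_f1_always_shares_without_somatic_change():
    model = GenealogyModel(
        hypothesis="parent_f1", n_loci=40, locus_lengths=[600] * 40,
        somatic_rate=0.0, seed=11,
    )
    _, _, truth = simulate_ancestry(model)
    assert truth.sharing_fraction == 1.0


def test_full_sibling_sharing_matches_mendelian_enumeration():
    # Oracle: with four distinct parental alleles, enumerate the 16 equally
    # likely transmission outcomes; the siblings share an allele in 12.
    shared = 0
    for a1 in range(2):
        for a2 in range(2):
            for b1 in range(2):
                for b2 in range(2):
                    shared += (a1 == b1) or (a2 == b2)
    expected = shared / 16
    assert expected == 0.75
    # Monte-Carlo check: high het rate makes all four parental alleles
    # distinct at every locus with near certainty.
    model = GenealogyModel(
        hypothesis="full_siblings", n_loci=400, locus_lengths=[300] * 400,
        ancestral_het_rate=0.05, somatic_rate=0.0, seed=5,
    )
    _, _, truth = simulate_ancestry(model)
    se = np.sqrt(0.75 * 0.25 / 400)
    assert abs(truth.sharing_fraction - expected) < 4 * se


def test_unrelated_lineages_never_share_at_kb_scale():
    model = GenealogyModel(
        hypothesis="unrelated", n_loci=60, locus_lengths=[999] * 60,
        ancestral_het_rate=0.01, somatic_rate=0.0, seed=7,
    )
    _, _, truth = simulate_ancestry(model)
    assert truth.sharing_fraction < 0.1


def test_truth_class_recomputable_from_emitted_haplotypes():
    for seed in (1, 2, 3):
        for hyp in ("parent_f1", "full_siblings", "unrelated", "selfing"):
            model = GenealogyModel(
                hypothesis=hyp, n_loci=10, locus_lengths=[300] * 10,
                somatic_rate=0.5, seed=seed,
            )
            loci_a, loci_b, truth = simulate_ancestry(model)
            for la, lb, t in zip(loci_a, loci_b, truth.loci):
                cls, min_d = sharing_class_from_haplotypes(
                    (la.hap1, la.hap2), (lb.hap1, lb.hap2)
                )
                assert cls == t.sharing_class
                if cls == "four_distinct":
                    assert min_d == t.min_unshared_distance >= 1


class TestPreset30:
    def test_planted_truth_counts(self, preset):
        t = preset.truth
        assert t.total_polymorphic == 254
        assert t.n_shared == 24 and t.n_four_distinct == 6
        assert t.sharing_fraction == 0.8
        assert t.total_min_unshared == 8
        assert t.total_expected_blocks == 30 + 7
        total = sum(loc.length for loc in t.loci)
        assert 28500 <= total <= 29500 and all(loc.length % 3 == 0 for loc in t.loci)

    def test_truth_classes_recomputable(self, preset):
        for t in preset.truth.loci:
            cls, _ = sharing_class_from_haplotypes(t.haps_a, t.haps_b)
            assert cls == t.sharing_class

    def test_deterministic_structure(self, preset):
        again = simulate.make_preset30()
        assert [l.hap1 for l in again.loci_a] == [l.hap1 for l in preset.loci_a]
        assert again.gap_positions == preset.gap_positions

    def test_gap_loci_have_het_sites_on_both_flanks_in_both_lineages(self, preset):
        for t in preset.truth.loci:
            for g in t.gap_positions:
                for hets in (t.het_positions_a, t.het_positions_b):
                    assert any(p < g for p in hets) and any(p > g for p in hets)

    def test_reads_avoid_planted_gaps(self, preset):
        rna, gen = simulate.simulate_preset_reads(preset, "A", seed=3)
        frags = {}
        for read in rna + gen:
            lo, hi = frags.get(read.pair_id, (read.start, read.ref_end))
            frags[read.pair_id] = (min(lo, read.start), max(hi, read.ref_end))
        by_locus = {}
        for read in rna + gen:
            by_locus[read.pair_id] = read.locus_id
        for pair_id, (lo, hi) in frags.items():
            for g in preset.gap_positions[by_locus[pair_id]]:
                assert not (lo < g < hi)


def test_simulate_reads_preconditions(preset):
    with pytest.raises(ValueError):
        simulate_reads(preset.loci_a, 0.0, 75, 180, 20, 0.0,
                       np.random.default_rng(0))


def test_het_site_allele_balance_error_free():
    locus = DiploidLocus("loc", "A", "A" * 300 + "C" + "A" * 299,
                         "A" * 300 + "G" + "A" * 299)
    rng = np.random.default_rng(42)
    reads = simulate_reads([locus], 100.0, 75, 180, 20, 0.0, rng)
    pile = pileup(reads, SequenceRecord("loc", locus.hap1))
    c, g = pile.counts[300, 1], pile.counts[300, 2]
    depth = c + g
    lo, hi = stats.binom.interval(0.99, depth, 0.5)
    assert lo <= c <= hi


def test_background_planted_counts_binomial():
    bg = simulate_genome_background(1_000_000, het_rate=0.01, indel_rate=0.001, seed=9)
    assert abs(bg.n_snps - 10_000) < 3 * np.sqrt(10_000 * 0.99)
    assert abs(bg.n_indels - 1_000) < 3 * np.sqrt(1_000)
    bg0 = simulate_genome_background(10_000, het_rate=0.0, indel_rate=0.0, seed=9)
    assert bg0.n_snps == 0 and bg0.n_indels == 0
    with pytest.raises(ValueError):
        simulate_genome_background(500)


def test_divergent_pairs_match_planted_counts():
    from clonelineage import divergence

    pairs, truth = simulate.simulate_divergent_pairs(20, 200, 0.03, 0.4, seed=4)
    for (a, b), sd, nd in zip(pairs, truth["sd"], truth["nd"]):
        est = divergence.ng86_pair(a, b)
        assert est.Sd == pytest.approx(sd)
        assert est.Nd == pytest.approx(nd)
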