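"""Scaffold classification rules: GC bands, endosymbiont criteria,
redundancy, overlap joining, size cutoff."""

import numpy as np
import pytest

from clonelineage.scaffolds import (
    FilterConfig,
    OverlapEvidence,
    ScaffoldRecord,
    apply_size_cutoff,
    classify_endosymbiont,
    exact_envelopment_matches,
    find_redundant,
    flag_gc_deviant,
    join_overlaps,
)


def _scaffold(sid, gc, cov=80.0, het=10.0, genes=None, length=5000):
    return ScaffoldRecord(
        id=sid, gc_fraction=gc, mean_coverage=cov, het_density=het,
        genes=genes or [], length=length,
    )


class TestGcDeviation:
    def test_host_like_gc_not_deviant(self):
        assert not flag_gc_deviant(_scaffold("s", 0.327))

    def test_below_band_deviant(self):
        assert flag_gc_deviant(_scaffold("s", 0.29))

    def test_boundaries_are_strict(self):
        assert not flag_gc_deviant(_scaffold("s", 0.30))
        assert not flag_gc_deviant(_scaffold("s", 0.35))
        assert flag_gc_deviant(_scaffold("s", 0.351))

    def test_all_n_scaffold_rejected(self):
        with pytest.raises(ValueError, match="GC undefined"):
            ScaffoldRecord(id="n", sequence="NNNNNN")


class TestEndosymbiont:
    def test_textbook_endosymbiont(self):
        s = _scaffold("e", 0.27, cov=15.0, het=0.0, genes=[("g", "bacterial")])
        assert classify_endosymbiont(s) == "endosymbiont"

    def test_single_eukaryotic_gene_forces_host(self):
        s = _scaffold("h", 0.27, cov=15.0, het=0.0,
                      genes=[("g1", "bacterial"), ("g2", "eukaryotic")])
        assert classify_endosymbiont(s) == "host"

    def test_expected_coverage_is_ambiguous(self):
        s = _scaffold("a", 0.27, cov=80.0, het=0.0)
        assert classify_endosymbiont(s) == "ambiguous"

    def test_gc_boundary_inclusive(self):
        s = _scaffold("e", 0.30, cov=15.0, het=0.0)
        assert classify_endosymbiont(s) == "endosymbiont"
        s31 = _scaffold("e", 0.31, cov=15.0, het=0.0)
        assert classify_endosymbiont(s31) == "ambiguous"

    def test_high_coverage_plasmid_like(self):
        s = _scaffold("p", 0.27, cov=400.0, het=0.0)
        assert classify_endosymbiont(s) == "endosymbiont"

    def test_never_endosymbiont_with_eukaryotic_gene(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            s = _scaffold(
                "x", float(rng.uniform(0.2, 0.4)), cov=float(rng.uniform(5, 200)),
                het=float(rng.uniform(0, 2)), genes=[("g", "eukaryotic")],
            )
            assert classify_endosymbiont(s) != "endosymbiont"

    def test_perfect_precision_and_recall_on_separated_mixture(self):
        rng = np.random.default_rng(4)
        hosts = [
            _scaffold(f"h{i}", float(rng.normal(0.33, 0.005)),
                      cov=float(rng.normal(80, 5)), het=float(rng.normal(10, 1)),
                      genes=[("g", "eukaryotic")])
            for i in range(40)
        ]
        endos = [
            _scaffold(f"e{i}", float(rng.normal(0.27, 0.005)),
                      cov=float(rng.normal(15, 2)), het=0.0,
                      genes=[("g", "bacterial")])
            for i in range(15)
        ]
        calls = {s.id: classify_endosymbiont(s) for s in hosts + endos}
        assert all(calls[s.id] == "host" for s in hosts)
        assert all(calls[s.id] == "endosymbiont" for s in endos)


class TestRedundancy:
    def test_exact_duplicate_removed_and_chain_resolves(self):
        base = "ACGT" * 2000
        c = ScaffoldRecord(id="c", sequence=base)
        b = ScaffoldRecord(id="b", sequence=base[:6000])
        a = ScaffoldRecord(id="a", sequence=base[:3000])
        matches = exact_envelopment_matches([a, b, c])
        assert find_redundant([a, b, c], matches) == ["a", "b"]

    def test_below_identity_threshold_kept(self):
        from clonelineage.scaffolds import ScaffoldMatch

        a = _scaffold("a", 0.33, length=3000)
        b = _scaffold("b", 0.33, length=9000)
        near = [ScaffoldMatch("a", "b", identity=0.97, coverage_of_smaller=1.0)]
        assert find_redundant([a, b], near) == []
        low_cov = [ScaffoldMatch("a", "b", identity=0.99, coverage_of_smaller=0.7)]
        assert find_redundant([a, b], low_cov) == []

    def test_idempotent(self):
        base = "ACGT" * 2000
        scaffs = [
            ScaffoldRecord(id="c", sequence=base),
            ScaffoldRecord(id="b", sequence=base[:6000]),
        ]
        matches = exact_envelopment_matches(scaffs)
        removed = find_redundant(scaffs, matches)
        survivors = [s for s in scaffs if s.id not in removed]
        again = find_redundant(survivors, exact_envelopment_matches(survivors))
        assert again == []


class TestJoin:
    def _pair(self):
        return (_scaffold("x", 0.33, length=5000), _scaffold("y", 0.33, length=4000))

    def test_clean_overlap_joined_with_correct_length(self):
        j = join_overlaps(self._pair(), OverlapEvidence(1500, 1.0, 20.0, True, False))
        assert j is not None and j.length == 5000 + 4000 - 1500

    def test_short_overlap_rejected(self):
        assert join_overlaps(self._pair(), OverlapEvidence(900, 1.0, 20.0, True, False)) is None

    def test_unexplained_mismatch_rejected(self):
        assert join_overlaps(self._pair(), OverlapEvidence(1500, 0.995, 20.0, False, False)) is None

    def test_conflicting_alignment_rejected(self):
        assert join_overlaps(self._pair(), OverlapEvidence(1500, 1.0, 20.0, True, True)) is None

    def test_low_coverage_or_identity_rejected(self):
        assert join_overlaps(self._pair(), OverlapEvidence(1500, 1.0, 5.0, True, False)) is None
        assert join_overlaps(self._pair(), OverlapEvidence(1500, 0.98, 20.0, True, False)) is None


def test_size_cutoff_strict_below_two_kb():
    scaffs = [_scaffold("u", 0.33, length=1999), _scaffold("v", 0.33, length=2000),
              _scaffold("w", 0.33, length=12345)]
    kept = apply_size_cutoff(scaffs)
    assert [s.id for s in kept] == ["v", "w"]
    assert apply_size_cutoff(kept) == kept  # idempotent


def test_gc_computed_over_non_n_bases():
    s = ScaffoldRecord(id="s", sequence="GGCCNNNNAATT")
    assert s.gc_fraction == pytest.approx(0.5)
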