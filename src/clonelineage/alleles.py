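"""Cross-lineage allele comparison and locus classification.

A locus is *shared_identical* when some reconstructed allele of lineage A
is nucleotide-identical to some allele of lineage B over the full compared
span; with several phased blocks this means a single per-block haplotype
choice must produce identical full-length sequences (block label swaps are
free, so the search runs over all per-block assignments). Loci with no
identical cross-lineage pair carry four distinct alleles; the substitution
count of the closest cross-lineage pair is then of interest because fixed
somatic mutations are expected to separate otherwise-identical alleles by
only a few substitutions. Loci whose block structure is too fragmented to
support the comparison are labelled indeterminate rather than guessed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .phasing import PhasedBlock


@dataclass
class LocusComparison:
    """Classification of one locus across the two lineages."""

    locus_id: str
    sharing_class: str  # shared_identical | four_distinct | indeterminate
    alleles_a: tuple[str, str] | None
    alleles_b: tuple[str, str] | None
    min_unshared_distance: int | None
    shared_pairing: tuple[int, int] | None = None
    n_blocks_a: int = 0
    n_blocks_b: int = 0
    note: str = ""


def _hamming(x: str, y: str) -> int:
    if len(x) != len(y):
        raise ValueError("allele spans differ in length")
    return sum(a != b for a, b in zip(x, y))


def _assemble(consensus: str, blocks: list[PhasedBlock], choice: tuple[int, ...]) -> tuple[str, str]:
    """Full-length allele pair for one per-block haplotype assignment."""
    a1, a2 = list(consensus), list(consensus)
    for blk, c in zip(blocks, choice):
        haps = (blk.hap_a, blk.hap_b) if c == 0 else (blk.hap_b, blk.hap_a)
        for pos, x, y in zip(blk.positions, *haps):
            a1[pos] = x
            a2[pos] = y
    return "".join(a1), "".join(a2)


def compare_locus(
    blocks_a: list[PhasedBlock],
    blocks_b: list[PhasedBlock],
    consensus_a: str,
    consensus_b: str | None = None,
    locus_id: str | None = None,
    max_blocks: int = 6,
) -> LocusComparison:
    """Classify one locus from the two lineages' phased blocks.

    ``consensus_a``/``consensus_b`` supply the invariant positions (and any
    homozygous differences) of each lineage; they must cover the same span.
    Loci with more than ``max_blocks`` blocks in either lineage are labelled
    indeterminate: with that many independent blocks an apparent identical
    pair can always be assembled, so the comparison loses its meaning.
    """
    consensus_b = consensus_a if consensus_b is None else consensus_b
    if len(consensus_a) != len(consensus_b):
        raise ValueError("consensus spans differ in length")
    locus_id = locus_id or (
        blocks_a[0].locus_id if blocks_a else blocks_b[0].locus_id if blocks_b else "locus"
    )
    if len(blocks_a) > max_blocks or len(blocks_b) > max_blocks:
        return LocusComparison(
            locus_id=locus_id,
            sharing_class="indeterminate",
            alleles_a=None,
            alleles_b=None,
            min_unshared_distance=None,
            n_blocks_a=len(blocks_a),
            n_blocks_b=len(blocks_b),
            note=f"too fragmented ({len(blocks_a)}/{len(blocks_b)} blocks)",
        )
    combos_a = [
        _assemble(consensus_a, blocks_a, c)
        for c in itertools.product((0, 1), repeat=len(blocks_a))
    ]
    combos_b = [
        _assemble(consensus_b, blocks_b, c)
        for c in itertools.product((0, 1), repeat=len(blocks_b))
    ]
    best = None  # (distance, alleles_a, alleles_b, pairing)
    for pa, (x1, x2) in enumerate(combos_a):
        for pb, (y1, y2) in enumerate(combos_b):
            for ia, xa in enumerate((x1, x2)):
                for ib, yb in enumerate((y1, y2)):
                    d = _hamming(xa, yb)
                    cand = (d, ((x1, x2) if ia == 0 else (x2, x1)),
                            ((y1, y2) if ib == 0 else (y2, y1)), (pa, pb))
                    if best is None or d < best[0]:
                        best = cand
            if best is not None and best[0] == 0:
                break
        if best is not None and best[0] == 0:
            break
    d, alleles_a, alleles_b, pairing = best
    if d == 0:
        return LocusComparison(
            locus_id=locus_id,
            sharing_class="shared_identical",
            alleles_a=alleles_a,
            alleles_b=alleles_b,
            min_unshared_distance=None,
            shared_pairing=pairing,
            n_blocks_a=len(blocks_a),
            n_blocks_b=len(blocks_b),
        )
    return LocusComparison(
        locus_id=locus_id,
        sharing_class="four_distinct",
        alleles_a=alleles_a,
        alleles_b=alleles_b,
        min_unshared_distance=d,
        n_blocks_a=len(blocks_a),
        n_blocks_b=len(blocks_b),
    )


def classify_dataset(comparisons: list[LocusComparison]) -> dict:
    """Dataset-level sharing summary.

    fraction_shared is computed over determinate loci; the total unshared
    substitution count sums the closest-pair distances of four-allele loci.
    """
    if not comparisons:
        raise ValueError("no locus comparisons")
    n = len(comparisons)
    n_ind = sum(c.sharing_class == "indeterminate" for c in comparisons)
    n_shared = sum(c.sharing_class == "shared_identical" for c in comparisons)
    n_four = sum(c.sharing_class == "four_distinct" for c in comparisons)
    determinate = n - n_ind
    return {
        "n_loci": n,
        "n_indeterminate": n_ind,
        "n_shared": n_shared,
        "n_four_distinct": n_four,
        "fraction_shared": n_shared / determinate if determinate else float("nan"),
        "total_min_unshared_substitutions": sum(
            c.min_unshared_distance for c in comparisons if c.sharing_class == "four_distinct"
        ),
    }


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def aa_report(comparison: LocusComparison, domain_interval: tuple[int, int]) -> dict:
    """Amino-acid substitution counts within a codon-aligned domain interval.

    Reports pairwise AA differences within lineage A, within lineage B, and
    between the unshared alleles (the non-matching alleles of a shared
    locus, or the closest cross-lineage pair otherwise).
    """
    start, end = domain_interval
    if (end - start) % 3:
        raise ValueError("domain interval must be codon-aligned")
    if comparison.alleles_a is None or comparison.alleles_b is None:
        raise ValueError("comparison carries no allele sequences")
    a1, a2 = (s[start:end] for s in comparison.alleles_a)
    b1, b2 = (s[start:end] for s in comparison.alleles_b)
    pa1, pa2, pb1, pb2 = map(_translate, (a1, a2, b1, b2))
    within_a = _hamming(pa1, pa2)
    within_b = _hamming(pb1, pb2)
    if comparison.sharing_class == "shared_identical":
        # alleles are arranged so index 0 is the shared pair
        between_unshared = _hamming(pa2, pb2)
    else:
        between_unshared = min(
            _hamming(x, y) for x in (pa1, pa2) for y in (pb1, pb2)
        )
    return {
        "within_a": within_a,
        "within_b": within_b,
        "between_unshared": between_unshared,
        "interval": domain_interval,
    }


def scan_premature_stop(allele: str, frame: int = 0) -> list[tuple[int, float]]:
    """In-frame stop codons strictly before the terminal codon.

    Returns (codon index, truncation fraction), the fraction of the protein
    lost if translation stops there.
    """
    if len(allele) - frame < 3:
        raise ValueError("allele shorter than one codon")
    coding = allele[frame:]
    n_codons = len(coding) // 3
    protein = _translate(coding[: 3 * n_codons])
    hits = []
    for idx, aa in enumerate(protein[:-1]):
        if aa == "*":
            hits.append((idx, (n_codons - idx) / n_codons))
    return hits
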