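"""Stepwise scaffold classification: contaminants, endosymbiont, redundancy.

The assembly-cleanup rules implemented here: scaffolds whose GC content
falls outside the 30–35% band deviate from the host genome (whose GC sits
around 32.7%) and are contamination candidates; a candidate is attributed
to the rickettsial endosymbiont only if it jointly (I) contains no
eukaryotic gene, (II) has GC of 30% or below, (III) shows no haplotypic
variation, and (IV) has read coverage far from the expected host coverage
(e.g. ~15x against an expected 80x, or far above for plasmids). A scaffold
enveloped by a larger one at >=98% identity over >=80% of its length is
redundant; overlapping scaffold ends are joined only under strict evidence
(>=1 kb overlap, >=10x coverage, >=99% identity, every mismatch explained
by haplotypic variation, no conflicting alignment).

Boundary semantics follow the wording of each rule: the deviation band uses
strict inequalities ("below 30% and above 35%"), the endosymbiont GC rule
is inclusive ("30% or below").
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class ScaffoldRecord:
    """One assembly scaffold with the summaries the filters consume."""

    id: str
    sequence: str = ""
    length: int = 0
    gc_fraction: float | None = None
    mean_coverage: float = 0.0
    het_density: float = 0.0  # het sites per kb
    genes: list[tuple[str, str]] = field(default_factory=list)  # (gene_id, taxon)

    def __post_init__(self):
        if self.sequence and not self.length:
            self.length = len(self.sequence)
        if self.gc_fraction is None:
            if not self.sequence:
                raise ValueError(f"{self.id}: need sequence or gc_fraction")
            acgt = [b for b in self.sequence.upper() if b in "ACGT"]
            if not acgt:
                raise ValueError(f"{self.id}: GC undefined (all-N scaffold)")
            self.gc_fraction = sum(b in "GC" for b in acgt) / len(acgt)
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(f"{self.id}: gc_fraction out of range")

    @property
    def has_eukaryotic_gene(self) -> bool:
        return any(taxon == "eukaryotic" for _, taxon in self.genes)


@dataclass
class FilterConfig:
    gc_low: float = 0.30
    gc_high: float = 0.35
    endo_gc_max: float = 0.30
    expected_coverage: float = 80.0
    coverage_band: tuple[float, float] = (0.5, 2.0)
    endo_max_het_density: float = 0.5  # het sites per kb
    min_scaffold: int = 2000
    redundancy_identity: float = 0.98
    redundancy_coverage: float = 0.80
    join_min_overlap: int = 1000
    join_min_cov: float = 10.0
    join_identity: float = 0.99


def flag_gc_deviant(scaffold: ScaffoldRecord, config: FilterConfig | None = None) -> bool:
    """True iff GC is strictly below the band or strictly above it."""
    config = config or FilterConfig()
    return scaffold.gc_fraction < config.gc_low or scaffold.gc_fraction > config.gc_high


def classify_endosymbiont(
    scaffold: ScaffoldRecord, config: FilterConfig | None = None
) -> str:
    """Classify a scaffold as endosymbiont, host, or ambiguous.

    A scaffold with any eukaryotic gene is host, unconditionally. The
    endosymbiont label requires all four criteria; anything else is
    ambiguous. "Far from expected coverage" is operationalized as outside
    ``coverage_band`` times the expected coverage.
    """
    config = config or FilterConfig()
    if scaffold.has_eukaryotic_gene:
        return "host"
    lo = config.coverage_band[0] * config.expected_coverage
    hi = config.coverage_band[1] * config.expected_coverage
    coverage_aberrant = not (lo <= scaffold.mean_coverage <= hi)
    if (
        scaffold.gc_fraction <= config.endo_gc_max
        and scaffold.het_density < config.endo_max_het_density
        and coverage_aberrant
    ):
        return "endosymbiont"
    return "ambiguous"


@dataclass
class ScaffoldMatch:
    """An all-vs-all alignment summary between two scaffolds.

    ``coverage_of_smaller`` is the fraction of the smaller scaffold's length
    covered by the alignment.
    """

    query_id: str
    target_id: str
    identity: float
    coverage_of_smaller: float


def find_redundant(
    scaffolds: list[ScaffoldRecord],
    matches: list[ScaffoldMatch],
    config: FilterConfig | None = None,
) -> list[str]:
    """Scaffolds enveloped by a strictly larger one at the identity and
    coverage thresholds. The larger member of a removing pair is never
    removed by that pair (removal is stable under chains a ⊂ b ⊂ c)."""
    config = config or FilterConfig()
    lengths = {s.id: s.length for s in scaffolds}
    removed = set()
    for m in matches:
        if m.query_id not in lengths or m.target_id not in lengths:
            continue
        small, large = sorted((m.query_id, m.target_id), key=lambda i: (lengths[i], i))
        if lengths[small] >= lengths[large]:
            continue  # equal length: neither envelops the other
        if m.identity >= config.redundancy_identity and (
            m.coverage_of_smaller >= config.redundancy_coverage
        ):
            removed.add(small)
    return sorted(removed)


def exact_envelopment_matches(scaffolds: list[ScaffoldRecord]) -> list[ScaffoldMatch]:
    """Substring-based matches for synthetic fixtures.

    For each pair where the smaller sequence occurs verbatim inside the
    larger, emits identity 1.0 over the full smaller length. Real assemblies
    would use an aligner here; the filters only consume match summaries.
    """
    matches = []
    ordered = sorted(scaffolds, key=lambda s: len(s.sequence))
    for i, small in enumerate(ordered):
        for large in ordered[i + 1:]:
            if len(small.sequence) < len(large.sequence) and small.sequence in large.sequence:
                matches.append(
                    ScaffoldMatch(
                        query_id=small.id,
                        target_id=large.id,
                        identity=1.0,
                        coverage_of_smaller=1.0,
                    )
                )
    return matches


@dataclass
class OverlapEvidence:
    """Evidence for joining two scaffolds across an end overlap."""

    overlap_length: int
    identity: float
    mean_coverage: float
    mismatches_het_supported: bool
    conflicting_alignment: bool


def join_overlaps(
    pair: tuple[ScaffoldRecord, ScaffoldRecord],
    evidence: OverlapEvidence,
    config: FilterConfig | None = None,
) -> ScaffoldRecord | None:
    """Join two scaffolds across an overlap when every rule holds.

    Requires overlap >= 1 kb at >= 10x coverage and >= 99% identity, all
    mismatches attributable to haplotypic variation, and no conflicting
    alignment. Returns the joined scaffold or None (rejection)."""
    config = config or FilterConfig()
    a, b = pair
    ok = (
        evidence.overlap_length >= config.join_min_overlap
        and evidence.mean_coverage >= config.join_min_cov
        and evidence.identity >= config.join_identity
        and evidence.mismatches_het_supported
        and not evidence.conflicting_alignment
    )
    if not ok:
        return None
    joined_len = a.length + b.length - evidence.overlap_length
    sequence = ""
    if a.sequence and b.sequence:
        sequence = a.sequence + b.sequence[evidence.overlap_length:]
    gc = (
        (a.gc_fraction * a.length + b.gc_fraction * (b.length - evidence.overlap_length))
        / joined_len
    )
    return ScaffoldRecord(
        id=f"{a.id}+{b.id}",
        sequence=sequence,
        length=joined_len,
        gc_fraction=gc if not sequence else None,
        mean_coverage=(a.mean_coverage + b.mean_coverage) / 2,
        het_density=(a.het_density * a.length + b.het_density * b.length)
        / (a.length + b.length),
        genes=a.genes + b.genes,
    )


def apply_size_cutoff(
    scaffolds: list[ScaffoldRecord], min_len: int = 2000
) -> list[ScaffoldRecord]:
    """Drop scaffolds shorter than ``min_len`` (>= min_len is kept)."""
    return [s for s in scaffolds if s.length >= min_len]
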