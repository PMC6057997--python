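"""Synthetic clonal diploid lineages, reads, and divergence fixtures.

Two vegetatively propagating diploid lineages are simulated under a stated
genealogy (parent–F1, full siblings, selfing line, or unrelated), with
post-split somatic point mutations fixed on single haplotypes. The simulator
emits haplotype/consensus FASTA, paired reads with alignments known by
construction (no mapper involved), and a machine-readable truth table, so
every downstream stage of the pipeline can be tested without external data.

Founder haplotypes are derived from a shared background sequence by
independent per-base mutation at half the ancestral heterozygosity rate, so
a diploid of two independent founders is heterozygous at about that rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import divergence
from .formats import AlignedRead, SequenceRecord

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

HYPOTHESES = ("parent_f1", "full_siblings", "selfing", "unrelated")

# Internal seed fixing the *structure* of the 30-locus preset (locus lengths,
# site positions, allele patterns). Read noise is controlled separately by
# the caller's seed, so the planted truth is one fixed object.
_PRESET_STRUCTURE_SEED = 731209


def _seq_to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _mutate(codes: np.ndarray, pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Return a copy with a random different base at each given position."""
    out = codes.copy()
    out[pos] = (out[pos] + rng.integers(1, 4, size=len(pos))) % 4
    return out


@dataclass
class GenealogyModel:
    """Parameters of a two-lineage genealogy simulation."""

    hypothesis: str = "full_siblings"
    n_loci: int = 30
    locus_lengths: list[int] | None = None
    ancestral_het_rate: float = 0.01
    somatic_rate: float = 0.13
    indel_rate: float = 0.001
    generations: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.hypothesis not in HYPOTHESES:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        for name in ("ancestral_het_rate", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.somatic_rate < 0:
            raise ValueError("somatic_rate must be non-negative")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.locus_lengths is None:
            self.locus_lengths = [999] * self.n_loci
        if len(self.locus_lengths) != self.n_loci:
            raise ValueError("locus_lengths must have n_loci entries")
        for L in self.locus_lengths:
            if L % 3:
                raise ValueError("locus lengths must be divisible by 3 (CDS)")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


@dataclass
class DiploidLocus:
    """One CDS locus of one lineage: two haplotype sequences plus provenance.

    provenance maps each variant position (0-based, locus coordinates) to an
    origin tag: ancestral_shared, ancestral_unshared, somatic_A, somatic_B.
    """

    locus_id: str
    lineage: str
    hap1: str
    hap2: str
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise ValueError(f"{self.locus_id}: haplotypes differ in length")

    @property
    def het_positions(self) -> list[int]:
        return [i for i, (a, b) in enumerate(zip(self.hap1, self.hap2)) if a != b]


@dataclass
class LocusTruth:
    locus_id: str
    length: int
    reference: str
    haps_a: tuple[str, str]
    haps_b: tuple[str, str]
    sharing_class: str
    min_unshared_distance: int
    n_polymorphic: int
    het_positions_a: list[int]
    het_positions_b: list[int]
    gap_positions: list[int]
    expected_blocks: int


@dataclass
class TruthTable:
    """Ground truth of a simulated two-lineage dataset."""

    loci: list[LocusTruth]
    hypothesis: str
    seed: int | None = None

    @property
    def total_polymorphic(self) -> int:
        return sum(t.n_polymorphic for t in self.loci)

    @property
    def total_expected_blocks(self) -> int:
        return sum(t.expected_blocks for t in self.loci)

    @property
    def n_shared(self) -> int:
        return sum(t.sharing_class == "shared_identical" for t in self.loci)

    @property
    def n_four_distinct(self) -> int:
        return sum(t.sharing_class == "four_distinct" for t in self.loci)

    @property
    def sharing_fraction(self) -> float:
        return self.n_shared / len(self.loci)

    @property
    def total_min_unshared(self) -> int:
        return sum(
            t.min_unshared_distance for t in self.loci if t.sharing_class == "four_distinct"
        )

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "seed": self.seed,
            "total_polymorphic": self.total_polymorphic,
            "total_expected_blocks": self.total_expected_blocks,
            "n_shared": self.n_shared,
            "n_four_distinct": self.n_four_distinct,
            "total_min_unshared": self.total_min_unshared,
            "loci": [
                {
                    "locus_id": t.locus_id,
                    "length": t.length,
                    "sharing_class": t.sharing_class,
                    "min_unshared_distance": t.min_unshared_distance,
                    "n_polymorphic": t.n_polymorphic,
                    "het_positions_a": t.het_positions_a,
                    "het_positions_b": t.het_positions_b,
                    "gap_positions": t.gap_positions,
                    "expected_blocks": t.expected_blocks,
                }
                for t in self.loci
            ],
        }


def sharing_class_from_haplotypes(
    haps_a: tuple[str, str], haps_b: tuple[str, str]
) -> tuple[str, int]:
    """Recompute (sharing class, min unshared distance) from four alleles.

    shared_identical if any cross-lineage pair is nucleotide-identical;
    otherwise four_distinct, with the minimum Hamming distance over the
    four cross-lineage pairs.
    """
    dists = []
    for a in haps_a:
        for b in haps_b:
            dists.append(sum(x != y for x, y in zip(a, b)))
    if min(dists) == 0:
        shared = 0
        return "shared_identical", shared
    return "four_distinct", min(dists)


# ---------------------------------------------------------------------------
# Site-level genealogy core (fast path shared with the genealogy module)


@dataclass
class _SiteLocus:
    """Variant-site view of one locus: positions plus the four allele columns."""

    length: int
    positions: np.ndarray  # sorted variant positions
    a1: np.ndarray  # base codes at positions, lineage A haplotype 1
    a2: np.ndarray
    b1: np.ndarray
    b2: np.ndarray
    consensus_a: np.ndarray | None = None
    consensus_b: np.ndarray | None = None

    def shares_allele(self) -> bool:
        for x in (self.a1, self.a2):
            for y in (self.b1, self.b2):
                if np.array_equal(x, y):
                    return True
        return False

    def consensus_differs(self) -> bool:
        """Whether the two lineages' assembly consensus sequences differ.

        An assembler emits one arbitrary allele per heterozygous site, so
        the consensus is a per-site pick between the two haplotypes (drawn
        once at simulation time).
        """
        return not np.array_equal(self.consensus_a, self.consensus_b)


def _founder(ref: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    pos = np.flatnonzero(rng.random(len(ref)) < rate)
    return _mutate(ref, pos, rng)


def _simulate_site_locus(
    length: int, model: GenealogyModel, rng: np.random.Generator
) -> _SiteLocus:
    ref = np.zeros(length, dtype=np.uint8)  # background cancels in comparisons
    half = model.ancestral_het_rate / 2.0
    hyp = model.hypothesis
    if hyp == "parent_f1":
        h1, h2 = _founder(ref, half, rng), _founder(ref, half, rng)
        novel = _founder(ref, half, rng)
        inherited = (h1, h2)[rng.integers(2)]
        a1, a2 = h1, h2
        b1, b2 = inherited.copy(), novel
    elif hyp == "full_siblings":
        p1 = (_founder(ref, half, rng), _founder(ref, half, rng))
        p2 = (_founder(ref, half, rng), _founder(ref, half, rng))
        a1, a2 = p1[rng.integers(2)].copy(), p2[rng.integers(2)].copy()
        b1, b2 = p1[rng.integers(2)].copy(), p2[rng.integers(2)].copy()
    elif hyp == "unrelated":
        a1, a2 = _founder(ref, half, rng), _founder(ref, half, rng)
        b1, b2 = _founder(ref, half, rng), _founder(ref, half, rng)
    elif hyp == "selfing":
        parent = (_founder(ref, half, rng), _founder(ref, half, rng))
        def _self_line(pair):
            cur = pair
            for _ in range(model.generations):
                cur = (cur[rng.integers(2)], cur[rng.integers(2)])
            return cur[0].copy(), cur[1].copy()
        a1, a2 = _self_line(parent)
        b1, b2 = _self_line(parent)
    else:  # pragma: no cover
        raise AssertionError(hyp)
    # somatic substitutions: Poisson per lineage, each fixed on one haplotype;
    # positions already variant are redrawn to keep sites biallelic
    haps = {"A": [a1, a2], "B": [b1, b2]}
    somatic_tags: dict[int, str] = {}
    for lineage in "AB":
        for _ in range(rng.poisson(model.somatic_rate)):
            for _attempt in range(50):
                pos = int(rng.integers(length))
                col = {a1[pos], a2[pos], b1[pos], b2[pos]}
                if len(col) == 1 and pos not in somatic_tags:
                    break
            hap = haps[lineage][rng.integers(2)]
            hap[pos] = (hap[pos] + rng.integers(1, 4)) % 4
            somatic_tags[pos] = f"somatic_{lineage}"
    stack = np.vstack([a1, a2, b1, b2])
    var = np.flatnonzero((stack != stack[0]).any(axis=0))
    pick_a = rng.integers(0, 2, size=len(var))
    pick_b = rng.integers(0, 2, size=len(var))
    locus = _SiteLocus(
        length=length,
        positions=var,
        a1=a1[var].copy(),
        a2=a2[var].copy(),
        b1=b1[var].copy(),
        b2=b2[var].copy(),
        consensus_a=np.where(pick_a == 0, a1[var], a2[var]),
        consensus_b=np.where(pick_b == 0, b1[var], b2[var]),
    )
    locus._somatic_tags = somatic_tags  # type: ignore[attr-defined]
    return locus


def simulate_ancestry(
    model: GenealogyModel, rng: np.random.Generator | None = None
) -> tuple[list[DiploidLocus], list[DiploidLocus], TruthTable]:
    """Simulate the two lineages' loci under the model's genealogy.

    Returns per-lineage loci with full sequences and a truth table whose
    sharing classes are recomputed from the emitted haplotypes.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    loci_a, loci_b, truths = [], [], []
    for i, length in enumerate(model.locus_lengths):
        sl = _simulate_site_locus(length, model, rng)
        background = _random_codes(rng, length)
        locus_id = f"locus_{i:03d}"
        seqs = {}
        for name, col in (("a1", sl.a1), ("a2", sl.a2), ("b1", sl.b1), ("b2", sl.b2)):
            codes = background.copy()
            codes[sl.positions] = (background[sl.positions] + col) % 4
            seqs[name] = _seq_to_str(codes)
        somatic = getattr(sl, "_somatic_tags", {})
        stack = np.vstack([sl.a1, sl.a2, sl.b1, sl.b2])
        provenance = {}
        for j, pos in enumerate(sl.positions):
            pos = int(pos)
            if pos in somatic:
                provenance[pos] = somatic[pos]
            else:
                in_a = {stack[0, j], stack[1, j]}
                in_b = {stack[2, j], stack[3, j]}
                provenance[pos] = (
                    "ancestral_shared" if (in_a & in_b) - {0} or (0 in in_a and 0 in in_b)
                    else "ancestral_unshared"
                )
        loc_a = DiploidLocus(locus_id, "A", seqs["a1"], seqs["a2"], dict(provenance))
        loc_b = DiploidLocus(locus_id, "B", seqs["b1"], seqs["b2"], dict(provenance))
        cls, min_d = sharing_class_from_haplotypes(
            (seqs["a1"], seqs["a2"]), (seqs["b1"], seqs["b2"])
        )
        truths.append(
            LocusTruth(
                locus_id=locus_id,
                length=length,
                reference=seqs["a1"],
                haps_a=(seqs["a1"], seqs["a2"]),
                haps_b=(seqs["b1"], seqs["b2"]),
                sharing_class=cls,
                min_unshared_distance=min_d,
                n_polymorphic=len(sl.positions),
                het_positions_a=[int(p) for p in sl.positions[sl.a1 != sl.a2]],
                het_positions_b=[int(p) for p in sl.positions[sl.b1 != sl.b2]],
                gap_positions=[],
                expected_blocks=1,
            )
        )
        loci_a.append(loc_a)
        loci_b.append(loc_b)
    return loci_a, loci_b, TruthTable(loci=truths, hypothesis=model.hypothesis, seed=model.seed)


# ---------------------------------------------------------------------------
# The 30-locus preset


@dataclass
class ReadConfig:
    coverage: float
    read_len: int
    insert_mean: float
    insert_sd: float
    error_rate: float
    source: str


@dataclass
class Preset30:
    """Deterministic 30-locus configuration with planted truth.

    30 CDS loci totalling ~29 kb carry exactly 254 polymorphic sites; 24
    loci share an identical allele across the lineages and 6 carry four
    distinct alleles whose closest cross-lineage pairs differ by 8
    substitutions in total; 7 fragment-uncoverable gaps make the true
    phase-block count 37.
    """

    loci_a: list[DiploidLocus]
    loci_b: list[DiploidLocus]
    reference: list[SequenceRecord]
    truth: TruthTable
    gap_positions: dict[str, list[int]]
    rna_reads: ReadConfig
    genomic_reads: ReadConfig


# locus roles in the preset (indices into the 30 loci)
_FD_LOCI = (3, 8, 13, 19, 24, 28)          # four distinct alleles
_FD_CLOSE_SUBS = (1, 1, 1, 2, 1, 2)        # somatic substitutions, total 8
_GAP_LOCI = (1, 5, 10, 15, 21, 26, 29)     # one uncoverable joint each
_WIDE_LOCI = (2, 7, 12, 17, 23)            # joint too wide for RNA fragments
_FD_DIVERGENT_SITES = 7                    # per second allele

_MARGIN = 100          # no het sites this close to a locus end (edge coverage)
_GAP_SPACING = 300     # distance across an uncoverable joint
_WIDE_SPACING = 320    # RNA fragments cannot span this, genomic ones can
_TOTAL_SITES = 254
_TOTAL_CODONS = 9667   # 29,001 bases


def _preset_lengths() -> list[int]:
    fd_codons = [220, 223, 226, 229, 232, 235]
    shared = [280 + (i * 53) % 140 for i in range(24)]
    shared[-1] -= sum(shared) + sum(fd_codons) - _TOTAL_CODONS
    codons = []
    fd_iter, sh_iter = iter(fd_codons), iter(shared)
    for i in range(30):
        codons.append(next(fd_iter) if i in _FD_LOCI else next(sh_iter))
    return [3 * c for c in codons]


def _allocate_sites(lengths: list[int]) -> list[int]:
    """Split the non-four-distinct site budget proportionally to length."""
    fd_sites = {
        i: k + 2 * _FD_DIVERGENT_SITES for i, k in zip(_FD_LOCI, _FD_CLOSE_SUBS)
    }
    budget = _TOTAL_SITES - sum(fd_sites.values())
    shared_idx = [i for i in range(30) if i not in _FD_LOCI]
    total_len = sum(lengths[i] for i in shared_idx)
    raw = {i: budget * lengths[i] / total_len for i in shared_idx}
    counts = {i: max(4, int(raw[i])) for i in shared_idx}
    # largest-remainder top-up to hit the budget exactly
    while sum(counts.values()) < budget:
        i = max(shared_idx, key=lambda j: (raw[j] - counts[j], -j))
        counts[i] += 1
    while sum(counts.values()) > budget:
        i = min(
            (j for j in shared_idx if counts[j] > 4),
            key=lambda j: (raw[j] - counts[j], j),
        )
        counts[i] -= 1
    return [fd_sites.get(i, counts.get(i, 0)) for i in range(30)]


def _place_sites(
    length: int, n: int, special: int | None, rng: np.random.Generator
) -> tuple[list[int], int | None]:
    """Place n het sites in [margin, length-margin] with one optional wide
    joint of the given spacing; returns positions and the joint index."""
    span = length - 2 * _MARGIN
    joint = (n - 1) // 2 if special else None
    spacings = []
    rest = span - (special or 0)
    n_rest = n - 1 - (1 if special else 0)
    base = rest / max(n_rest, 1)
    for j in range(n - 1):
        if joint is not None and j == joint:
            spacings.append(special)
        else:
            spacings.append(base)
    # deterministic jitter, preserving the total span and min spacing
    jitter = rng.uniform(-min(10.0, base / 4), min(10.0, base / 4), size=n - 1)
    jitter -= jitter.mean()
    positions = [float(_MARGIN)]
    for j, s in enumerate(spacings):
        positions.append(positions[-1] + s + (0.0 if j == joint else jitter[j]))
    pos = sorted({int(round(p)) for p in positions})
    while len(pos) < n:  # collision after rounding: nudge
        pos.append(pos[-1] + 8)
        pos = sorted(set(pos))
    return pos[:n], joint


def make_preset30() -> Preset30:
    """Build the deterministic 30-locus planted-truth configuration."""
    rng = np.random.default_rng(_PRESET_STRUCTURE_SEED)
    lengths = _preset_lengths()
    site_counts = _allocate_sites(lengths)
    fd_subs = dict(zip(_FD_LOCI, _FD_CLOSE_SUBS))
    loci_a, loci_b, truths, refs = [], [], [], []
    gap_positions: dict[str, list[int]] = {}
    for i in range(30):
        length, n = lengths[i], site_counts[i]
        locus_id = f"locus_{i:03d}"
        special = (
            _GAP_SPACING if i in _GAP_LOCI else _WIDE_SPACING if i in _WIDE_LOCI else None
        )
        positions, joint = _place_sites(length, n, special, rng)
        ref = _random_cds(rng, length)
        a1, a2, b1, b2 = ref.copy(), ref.copy(), ref.copy(), ref.copy()
        provenance: dict[int, str] = {}
        if i in _FD_LOCI:
            k = fd_subs[i]
            roles = _fd_roles(n, k)
            for pos, role in zip(positions, roles):
                alt = (ref[pos] + rng.integers(1, 4)) % 4
                if role == "s":
                    a1[pos] = alt
                    provenance[pos] = "somatic_A"
                elif role == "a":
                    a2[pos] = alt
                    provenance[pos] = "ancestral_unshared"
                else:
                    b2[pos] = alt
                    provenance[pos] = "ancestral_unshared"
        else:
            roles = _shared_roles(n, joint)
            for pos, role in zip(positions, roles):
                alt = (ref[pos] + rng.integers(1, 4)) % 4
                if "y" in role:
                    a2[pos] = alt
                if "z" in role:
                    b2[pos] = alt
                provenance[pos] = "ancestral_unshared"
        gaps = []
        if i in _GAP_LOCI:
            gaps = [int((positions[joint] + positions[joint + 1]) // 2)]
        gap_positions[locus_id] = gaps
        seqs = {k: _seq_to_str(v) for k, v in (("a1", a1), ("a2", a2), ("b1", b1), ("b2", b2))}
        cls, min_d = sharing_class_from_haplotypes(
            (seqs["a1"], seqs["a2"]), (seqs["b1"], seqs["b2"])
        )
        truths.append(
            LocusTruth(
                locus_id=locus_id,
                length=length,
                reference=_seq_to_str(ref),
                haps_a=(seqs["a1"], seqs["a2"]),
                haps_b=(seqs["b1"], seqs["b2"]),
                sharing_class=cls,
                min_unshared_distance=min_d,
                n_polymorphic=n,
                het_positions_a=[p for p in positions if seqs["a1"][p] != seqs["a2"][p]],
                het_positions_b=[p for p in positions if seqs["b1"][p] != seqs["b2"][p]],
                gap_positions=gaps,
                expected_blocks=2 if gaps else 1,
            )
        )
        refs.append(SequenceRecord(id=locus_id, sequence=_seq_to_str(ref)))
        loci_a.append(DiploidLocus(locus_id, "A", seqs["a1"], seqs["a2"], dict(provenance)))
        loci_b.append(DiploidLocus(locus_id, "B", seqs["b1"], seqs["b2"], dict(provenance)))
    truth = TruthTable(loci=truths, hypothesis="full_siblings", seed=None)
    assert truth.total_polymorphic == _TOTAL_SITES
    assert truth.n_four_distinct == len(_FD_LOCI)
    assert truth.total_min_unshared == sum(_FD_CLOSE_SUBS)
    assert truth.total_expected_blocks == 30 + len(_GAP_LOCI)
    return Preset30(
        loci_a=loci_a,
        loci_b=loci_b,
        reference=refs,
        truth=truth,
        gap_positions=gap_positions,
        rna_reads=ReadConfig(35.0, 75, 180.0, 20.0, 0.001, "rna"),
        genomic_reads=ReadConfig(80.0, 150, 450.0, 50.0, 0.001, "genomic"),
    )


def _random_cds(rng: np.random.Generator, length: int) -> np.ndarray:
    """A random open reading frame: sense codons only (no internal stops)."""
    sense = divergence.SENSE_CODONS
    idx = rng.integers(0, len(sense), size=length // 3)
    seq = "".join(sense[i] for i in idx)
    return np.array([_CODE[b] for b in seq], dtype=np.uint8)


def _fd_roles(n: int, k: int) -> list[str]:
    """Interleave somatic (s), A-divergent (a) and B-divergent (b) sites."""
    counts = {"a": _FD_DIVERGENT_SITES, "b": _FD_DIVERGENT_SITES, "s": k}
    roles = []
    order = ["a", "b", "s"]
    while len(roles) < n:
        for r in order:
            if counts[r] > 0:
                counts[r] -= 1
                roles.append(r)
    return roles[:n]


def _shared_roles(n: int, joint: int | None) -> list[str]:
    """Alternate variants between the two unshared alleles, restarting the
    alternation after an uncoverable joint so both flanks stay informative
    for both lineages."""
    sides = [list(range(n))] if joint is None else [
        list(range(joint + 1)), list(range(joint + 1, n))
    ]
    roles = [""] * n
    for side in sides:
        for j, idx in enumerate(side):
            roles[idx] = ("y", "z", "yz")[j % 2 if j < 2 else (2 if j % 3 == 2 else j % 2)]
    return roles


# ---------------------------------------------------------------------------
# Read simulation (alignments by construction)


def _error_quality(error_rate: float) -> int:
    if error_rate <= 0:
        return 40
    return min(40, int(round(-10 * np.log10(error_rate))))


def simulate_reads(
    loci: list[DiploidLocus],
    coverage: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    rng: np.random.Generator,
    source: str = "genomic",
    uncoverable: dict[str, list[int]] | None = None,
) -> list[AlignedRead]:
    """Draw paired fragments 50:50 from the two haplotypes of each locus.

    Fragments that would span a position listed in ``uncoverable`` are
    redrawn, emulating stretches no sequencing library covered. Sequencing
    errors are i.i.d. substitutions; base qualities reflect the error rate.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    reads: list[AlignedRead] = []
    qual = _error_quality(error_rate)
    for locus in loci:
        L = len(locus.hap1)
        if read_len >= L:
            raise ValueError(f"{locus.locus_id}: read length {read_len} >= locus {L}")
        gaps = (uncoverable or {}).get(locus.locus_id, [])
        n_frag = int(round(L * coverage / (2 * read_len)))
        haps = (
            np.frombuffer(locus.hap1.encode(), dtype=np.uint8),
            np.frombuffer(locus.hap2.encode(), dtype=np.uint8),
        )
        for f in range(n_frag):
            for _attempt in range(200):
                insert = int(round(rng.normal(insert_mean, insert_sd)))
                insert = max(read_len, min(insert, L))
                start = int(rng.integers(0, L - insert + 1))
                if not any(start < g < start + insert for g in gaps):
                    break
            hap_idx = int(rng.integers(2))
            hap = haps[hap_idx]
            pair_id = f"{locus.locus_id}:{source}:{f}:h{hap_idx + 1}"
            for mate, (s, e) in enumerate(
                ((start, start + read_len), (start + insert - read_len, start + insert))
            ):
                seq = hap[s:e].copy()
                quals = np.full(e - s, qual, dtype=np.uint8)
                if error_rate > 0:
                    n_err = rng.binomial(e - s, error_rate)
                    if n_err:
                        err_pos = rng.choice(e - s, size=n_err, replace=False)
                        offs = rng.integers(1, 4, size=n_err).astype(np.uint8)
                        for p, o in zip(err_pos, offs):
                            seq[p] = _BASE_ARR[(_CODE[chr(seq[p])] + o) % 4]
                reads.append(
                    AlignedRead(
                        read_id=f"{pair_id}/{mate + 1}",
                        pair_id=pair_id,
                        locus_id=locus.locus_id,
                        start=s,
                        sequence=seq.tobytes().decode(),
                        qualities=quals,
                        cigar=[("M", e - s)],
                        source=source,
                        is_read1=(mate == 0),
                    )
                )
    return reads


def simulate_preset_reads(
    preset: Preset30, lineage: str, seed: int
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """RNA-like and genomic-like read sets for one lineage of the preset."""
    rng = np.random.default_rng([seed, 0 if lineage == "A" else 1])
    loci = preset.loci_a if lineage == "A" else preset.loci_b
    out = []
    for cfg in (preset.rna_reads, preset.genomic_reads):
        out.append(
            simulate_reads(
                loci,
                coverage=cfg.coverage,
                read_len=cfg.read_len,
                insert_mean=cfg.insert_mean,
                insert_sd=cfg.insert_sd,
                error_rate=cfg.error_rate,
                rng=rng,
                source=cfg.source,
                uncoverable=preset.gap_positions,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Diploid genome background (het SNPs + indels on a long scaffold)


@dataclass
class _HapSegments:
    """Alignment of one haplotype to the reference as M/I segments."""

    codes: np.ndarray
    hap_starts: np.ndarray  # segment start in haplotype coords
    ref_starts: np.ndarray  # segment start in reference coords (-1: insertion)
    lengths: np.ndarray


@dataclass
class BackgroundTruth:
    reference: SequenceRecord
    snp_positions: np.ndarray
    indel_anchors: np.ndarray
    n_snps: int
    n_indels: int
    hap0: _HapSegments
    hap1: _HapSegments


def simulate_genome_background(
    length: int,
    het_rate: float = 0.01,
    indel_rate: float = 0.001,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> BackgroundTruth:
    """A diploid scaffold with planted heterozygous SNPs and indels.

    Haplotype 0 equals the reference; haplotype 1 carries het SNPs at
    ``het_rate`` and het indels at ``indel_rate`` (insertion/deletion 50:50,
    geometric lengths with mean 2).
    """
    if length < 1000:
        raise ValueError("background scaffold must be at least 1 kb")
    if rng is None:
        rng = np.random.default_rng(seed)
    ref = _random_codes(rng, length)
    # indels first; keep them separated and away from scaffold ends
    raw_anchor = np.flatnonzero(rng.random(length) < indel_rate)
    raw_anchor = raw_anchor[(raw_anchor > 50) & (raw_anchor < length - 50)]
    anchors, last = [], -100
    for a in raw_anchor:
        if a - last > 20:
            anchors.append(int(a))
            last = a
    indels = []  # (anchor, kind, length or bases)
    blocked = set()
    for a in anchors:
        size = int(rng.geometric(0.5))
        if rng.random() < 0.5:
            indels.append((a, "D", size))
            blocked.update(range(a, a + size + 2))
        else:
            indels.append((a, "I", _random_codes(rng, size)))
            blocked.update((a, a + 1))
    snp_pos = np.flatnonzero(rng.random(length) < het_rate)
    snp_pos = np.array([p for p in snp_pos if p not in blocked], dtype=np.int64)
    hap1_ref = ref.copy()
    hap1_ref[snp_pos] = (hap1_ref[snp_pos] + rng.integers(1, 4, size=len(snp_pos))) % 4
    # build hap1 segments: M blocks between indels, I blocks for insertions
    hap_starts, ref_starts, lens, chunks = [], [], [], []
    hpos, rpos = 0, 0
    for a, kind, payload in indels:
        seg = hap1_ref[rpos:a + 1]
        hap_starts.append(hpos); ref_starts.append(rpos); lens.append(len(seg))
        chunks.append(seg); hpos += len(seg)
        if kind == "D":
            rpos = a + 1 + payload
        else:
            hap_starts.append(hpos); ref_starts.append(-1); lens.append(len(payload))
            chunks.append(payload); hpos += len(payload)
            rpos = a + 1
    seg = hap1_ref[rpos:]
    hap_starts.append(hpos); ref_starts.append(rpos); lens.append(len(seg))
    chunks.append(seg)
    hap1 = _HapSegments(
        codes=np.concatenate(chunks),
        hap_starts=np.array(hap_starts),
        ref_starts=np.array(ref_starts),
        lengths=np.array(lens),
    )
    hap0 = _HapSegments(
        codes=ref.copy(),
        hap_starts=np.array([0]),
        ref_starts=np.array([0]),
        lengths=np.array([length]),
    )
    return BackgroundTruth(
        reference=SequenceRecord(id="scaffold_1", sequence=_seq_to_str(ref)),
        snp_positions=snp_pos,
        indel_anchors=np.array([a for a, _, _ in indels]),
        n_snps=len(snp_pos),
        n_indels=len(indels),
        hap0=hap0,
        hap1=hap1,
    )


def _read_from_segments(
    hap: _HapSegments, o: int, rl: int
) -> tuple[int, list[tuple[str, int]]]:
    """Reference start and CIGAR for a read at haplotype offset [o, o+rl)."""
    cigar: list[tuple[str, int]] = []
    ref_start = -1
    idx = int(np.searchsorted(hap.hap_starts, o, side="right")) - 1
    remaining, pos = rl, o
    last_ref_end = None
    while remaining > 0:
        hs, rs, ln = int(hap.hap_starts[idx]), int(hap.ref_starts[idx]), int(hap.lengths[idx])
        off = pos - hs
        take = min(remaining, ln - off)
        if rs < 0:
            cigar.append(("I", take))
        else:
            seg_ref = rs + off
            if last_ref_end is not None and seg_ref > last_ref_end:
                cigar.append(("D", seg_ref - last_ref_end))
            if ref_start < 0:
                ref_start = seg_ref
            cigar.append(("M", take))
            last_ref_end = seg_ref + take
        pos += take
        remaining -= take
        idx += 1
    # leading/trailing insertions align nothing: soft-clip them
    if cigar and cigar[0][0] == "I":
        cigar[0] = ("S", cigar[0][1])
    if cigar and cigar[-1][0] == "D":
        cigar.pop()
    if cigar and cigar[-1][0] == "I":
        cigar[-1] = ("S", cigar[-1][1])
    merged: list[tuple[str, int]] = []
    for op, n in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    return ref_start, merged


def simulate_background_reads(
    background: BackgroundTruth,
    coverage: float,
    read_len: int,
    insert_mean: float,
    insert_sd: float,
    error_rate: float,
    rng: np.random.Generator,
    source: str = "genomic",
) -> list[AlignedRead]:
    """Paired reads from the diploid background, with indel-aware CIGARs."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    qual = _error_quality(error_rate)
    reads: list[AlignedRead] = []
    haps = (background.hap0, background.hap1)
    scaffold = background.reference.id
    n_frag = int(round(len(background.reference.sequence) * coverage / (2 * read_len)))
    hap_lens = (len(haps[0].codes), len(haps[1].codes))
    hap_choice = rng.integers(0, 2, size=n_frag)
    inserts = np.clip(
        np.round(rng.normal(insert_mean, insert_sd, size=n_frag)).astype(int),
        read_len, min(hap_lens) - 1,
    )
    starts = (rng.random(n_frag) * (np.array([hap_lens[h] for h in hap_choice]) - inserts)).astype(int)
    err_counts = rng.binomial(read_len, error_rate, size=(n_frag, 2)) if error_rate > 0 else np.zeros((n_frag, 2), int)
    for f in range(n_frag):
        hap = haps[hap_choice[f]]
        insert, start = int(inserts[f]), int(starts[f])
        pair_id = f"{scaffold}:{source}:{f}:h{hap_choice[f]}"
        for mate, o in enumerate((start, start + insert - read_len)):
            seq = hap.codes[o:o + read_len].copy()
            n_err = int(err_counts[f, mate])
            if n_err:
                err_pos = rng.choice(read_len, size=n_err, replace=False)
                seq[err_pos] = (seq[err_pos] + rng.integers(1, 4, size=n_err).astype(np.uint8)) % 4
            ref_start, cigar = _read_from_segments(hap, o, read_len)
            if ref_start < 0:
                continue  # read entirely inside an insertion
            reads.append(
                AlignedRead(
                    read_id=f"{pair_id}/{mate + 1}",
                    pair_id=pair_id,
                    locus_id=scaffold,
                    start=ref_start,
                    sequence=_seq_to_str(seq),
                    qualities=np.full(read_len, qual, dtype=np.uint8),
                    cigar=cigar,
                    source=source,
                    is_read1=(mate == 0),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Collinear CDS pair fixtures for the dN/dS estimator


def simulate_divergent_pairs(
    n_pairs: int,
    n_codons: int,
    ds_true: float,
    omega_true: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    count_model: str = "fixed",
) -> tuple[list[tuple[str, str]], dict]:
    """CDS pairs diverged at configured synonymous/nonsynonymous rates.

    Substitution counts per pair are the expected counts given each
    sequence's site composition (``fixed``, with stochastic rounding so the
    mean is unbiased) or Poisson draws (``poisson``); positions and target
    codons are random, at most one substitution per codon.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    ps = divergence.inverse_jukes_cantor(ds_true)
    pn = divergence.inverse_jukes_cantor(ds_true * omega_true)
    syn_capable = [c for c in divergence.SENSE_CODONS if divergence.synonymous_changes(c)]
    pairs = []
    truth = {"ds_true": ds_true, "omega_true": omega_true, "sd": [], "nd": []}
    sense = list(divergence.SENSE_CODONS)
    for _ in range(n_pairs):
        codons = [sense[j] for j in rng.integers(0, len(sense), size=n_codons)]
        S = sum(divergence.codon_syn_sites(c) for c in codons)
        N = 3 * n_codons - S
        if count_model == "poisson":
            sd = int(rng.poisson(ps * S))
            nd = int(rng.poisson(pn * N))
        else:
            sd = int(ps * S) + (1 if rng.random() < (ps * S) % 1 else 0)
            nd = int(pn * N) + (1 if rng.random() < (pn * N) % 1 else 0)
        seq2 = list(codons)
        used: set[int] = set()
        placed_s = 0
        while placed_s < sd:
            j = int(rng.integers(n_codons))
            opts = divergence.synonymous_changes(codons[j])
            if j in used or not opts:
                continue
            seq2[j] = opts[int(rng.integers(len(opts)))]
            used.add(j)
            placed_s += 1
        placed_n = 0
        while placed_n < nd:
            j = int(rng.integers(n_codons))
            opts = divergence.nonsynonymous_changes(codons[j])
            if j in used or not opts:
                continue
            seq2[j] = opts[int(rng.integers(len(opts)))]
            used.add(j)
            placed_n += 1
        pairs.append(("".join(codons), "".join(seq2)))
        truth["sd"].append(sd)
        truth["nd"].append(nd)
    return pairs, truth
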