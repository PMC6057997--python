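"""Collinear-anchor chaining and Nei–Gojobori (1986) dN/dS estimation.

The NG86 method counts, for each codon, the fraction of possible single-base
changes that are synonymous ("synonymous sites"), tallies observed
synonymous/nonsynonymous differences between two aligned coding sequences
(averaging over all shortest mutational pathways for codons differing at more
than one position), and applies the Jukes–Cantor correction
d = -(3/4)·ln(1 - 4p/3) to the raw proportions. Changes that would create a
stop codon count as nonsynonymous, which keeps S + N = 3 × codon count.

Pairs with dS = 0, dN = 0, or saturated values (dS or dN >= 2, or an
undefined correction) are flagged and excluded from summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

STOP_CODONS = frozenset(standard_dna_table.stop_codons)
CODON_TO_AA = dict(standard_dna_table.forward_table)
SENSE_CODONS = tuple(sorted(CODON_TO_AA))


def _single_changes(codon: str):
    for pos in range(3):
        for base in BASES:
            if base != codon[pos]:
                yield pos, base, codon[:pos] + base + codon[pos + 1:]


@lru_cache(maxsize=None)
def codon_syn_sites(codon: str) -> float:
    """Number of synonymous sites in a codon (NG86; stops are nonsynonymous)."""
    if codon in STOP_CODONS or any(b not in BASES for b in codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    syn = 0
    for _, _, alt in _single_changes(codon):
        if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[codon]:
            syn += 1
    return syn / 3.0


def synonymous_changes(codon: str) -> list[str]:
    """Sense codons one substitution away encoding the same amino acid."""
    return [
        alt
        for _, _, alt in _single_changes(codon)
        if alt not in STOP_CODONS and CODON_TO_AA[alt] == CODON_TO_AA[codon]
    ]


def nonsynonymous_changes(codon: str) -> list[str]:
    """Sense codons one substitution away encoding a different amino acid."""
    return [
        alt
        for _, _, alt in _single_changes(codon)
        if alt not in STOP_CODONS and CODON_TO_AA[alt] != CODON_TO_AA[codon]
    ]


@lru_cache(maxsize=None)
def _pathway_counts(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons.

    Averages over all orderings of the differing positions; pathways passing
    through a stop codon are excluded (if every pathway is blocked, all are
    used — the standard fallback for this rare case).
    """
    diff = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = codon1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        syn = sum(
            1
            for a, b in steps
            if a not in STOP_CODONS
            and b not in STOP_CODONS
            and CODON_TO_AA.get(a) == CODON_TO_AA.get(b)
        )
        paths.append((blocked, syn, len(steps) - syn))
    open_paths = [(s, n) for blocked, s, n in paths if not blocked]
    if not open_paths:
        open_paths = [(s, n) for _, s, n in paths]
    sd = sum(s for s, _ in open_paths) / len(open_paths)
    nd = sum(n for _, n in open_paths) / len(open_paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; undefined (inf) at p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def inverse_jukes_cantor(d: float) -> float:
    """Raw difference proportion corresponding to a JC-corrected distance."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


@dataclass
class CodonPairEstimate:
    """NG86 quantities for one aligned CDS pair."""

    pair_id: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float | None
    flags: set = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return "ok" in self.flags


def ng86_pair(cds_1: str, cds_2: str, pair_id: str = "pair") -> CodonPairEstimate:
    """NG86 estimate between two equal-length, in-frame coding sequences.

    Codons containing N or a gap in either sequence are skipped. Internal
    stop codons are rejected (out-of-frame input is the usual cause).
    """
    if len(cds_1) != len(cds_2):
        raise ValueError("sequences differ in length")
    if len(cds_1) % 3:
        raise ValueError("length not divisible by 3")
    cds_1, cds_2 = cds_1.upper(), cds_2.upper()
    S = N = Sd = Nd = 0.0
    n_codons = 0
    n_total = len(cds_1) // 3
    for i in range(n_total):
        c1, c2 = cds_1[3 * i:3 * i + 3], cds_2[3 * i:3 * i + 3]
        if set(c1 + c2) - set(BASES):
            continue  # N or gap: skip codon
        internal = i < n_total - 1
        if internal and (c1 in STOP_CODONS or c2 in STOP_CODONS):
            raise ValueError(f"internal stop codon at codon {i}")
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue  # terminal stop: not a coding site
        n_codons += 1
        s = 0.5 * (codon_syn_sites(c1) + codon_syn_sites(c2))
        S += s
        N += 3.0 - s
        sd, nd = _pathway_counts(c1, c2)
        Sd += sd
        Nd += nd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    flags = set()
    if Sd == 0:
        flags.add("ds_zero")
    if Nd == 0:
        flags.add("dn_zero")
    if dS >= 2.0 or dN >= 2.0 or math.isinf(dS) or math.isinf(dN):
        flags.add("saturated")
    if not flags:
        flags.add("ok")
    omega = dN / dS if "ok" in flags else None
    return CodonPairEstimate(
        pair_id=pair_id, n_codons=n_codons, S=S, N=N, Sd=Sd, Nd=Nd,
        pS=pS, pN=pN, dS=dS, dN=dN, omega=omega, flags=flags,
    )


def filter_estimates(estimates: list[CodonPairEstimate]) -> list[CodonPairEstimate]:
    """Keep only unflagged pairs (drop dS=0, dN=0 and saturated estimates)."""
    return [e for e in estimates if e.ok]


def summarize_divergence(kept: list[CodonPairEstimate], threshold: float = 1.5) -> dict:
    """Summary statistics over filtered pairs.

    Both the mean of per-pair ratios and the ratio of mean rates are
    reported; with substitution counts this small per gene the two can
    differ noticeably, so downstream consumers get to pick.
    """
    if not kept:
        raise ValueError("no estimates to summarize")
    ds = np.array([e.dS for e in kept])
    dn = np.array([e.dN for e in kept])
    omega = np.array([e.omega for e in kept])
    return {
        "n": len(kept),
        "mean_dS": float(ds.mean()),
        "mean_dN": float(dn.mean()),
        "mean_omega": float(omega.mean()),
        "ratio_of_means": float(dn.mean() / ds.mean()),
        "n_above": int((omega > threshold).sum()),
        "threshold": threshold,
    }


def bin_log_ratios(kept: list[CodonPairEstimate], n_bins: int = 60):
    """Histogram of log10(dN/dS) over equal-width bins spanning the data."""
    omega = np.array([e.omega for e in kept], dtype=float)
    if len(omega) == 0:
        raise ValueError("no estimates to bin")
    counts, edges = np.histogram(np.log10(omega), bins=n_bins)
    return counts, edges


# ---------------------------------------------------------------------------
# Collinear chaining


@dataclass(frozen=True)
class GenePairAnchor:
    """A best-hit gene pair anchoring two genomes, by gene-order index."""

    pair_id: str
    scaffold_a: str
    index_a: int
    scaffold_b: str
    index_b: int

    def __post_init__(self):
        if self.index_a < 0 or self.index_b < 0:
            raise ValueError("gene-order indices must be non-negative")


@dataclass
class CollinearChain:
    """A syntenic run of anchors, monotone in gene order on both genomes."""

    anchors: list[GenePairAnchor]
    orientation: str  # "same" or "inverted"

    def __len__(self) -> int:
        return len(self.anchors)


def condense_tandem(anchors: list[GenePairAnchor]) -> list[GenePairAnchor]:
    """Collapse runs of anchors sharing a gene index on either genome.

    Tandem duplicates show up as several anchors pointing at the same gene
    position; one representative (the first in sorted order) is kept.
    """
    kept = []
    seen_a: set[int] = set()
    seen_b: set[int] = set()
    for a in sorted(anchors, key=lambda x: (x.index_a, x.index_b)):
        if a.index_a in seen_a or a.index_b in seen_b:
            continue
        seen_a.add(a.index_a)
        seen_b.add(a.index_b)
        kept.append(a)
    return kept


def _longest_chain(anchors: list[GenePairAnchor], max_gap: int, sign: int):
    """DP longest chain, increasing in A and (sign>0) increasing / (sign<0)
    decreasing in B, with at most max_gap intervening genes on each genome."""
    n = len(anchors)
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            da = anchors[j].index_a - anchors[i].index_a
            db = sign * (anchors[j].index_b - anchors[i].index_b)
            if da < 1 or db < 1:
                continue
            if da - 1 > max_gap or db - 1 > max_gap:
                continue
            if best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    end = max(range(n), key=lambda j: (best[j], -anchors[j].index_a)) if n else -1
    chain = []
    while end != -1:
        chain.append(anchors[end])
        end = prev[end]
    return chain[::-1]


def chain_collinear(
    anchors: list[GenePairAnchor], max_gap: int = 20, min_pairs: int = 5
) -> list[CollinearChain]:
    """Extract syntenic chains per scaffold pair.

    Tandem duplicates are condensed first. Chains are pulled out greedily:
    the longest chain (ties broken by smaller start index) is extracted,
    its anchors removed, and the search repeated until no chain reaches
    min_pairs.
    """
    by_pair: dict[tuple[str, str], list[GenePairAnchor]] = {}
    for a in anchors:
        by_pair.setdefault((a.scaffold_a, a.scaffold_b), []).append(a)
    chains = []
    for key in sorted(by_pair):
        pool = condense_tandem(by_pair[key])
        pool.sort(key=lambda x: (x.index_a, x.index_b))
        while True:
            fwd = _longest_chain(pool, max_gap, +1)
            rev = _longest_chain(pool, max_gap, -1)
            if len(fwd) >= len(rev):
                chain, orient = fwd, "same"
            else:
                chain, orient = rev, "inverted"
            if len(chain) < min_pairs:
                break
            chains.append(CollinearChain(anchors=chain, orientation=orient))
            used = set(id(a) for a in chain)
            pool = [a for a in pool if id(a) not in used]
    return chains
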