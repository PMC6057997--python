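"""Read-backed phasing of heterozygous sites into blocks.

The manual procedure this formalizes is tracing overlapping reads and their
mates from SNP to SNP: two het sites end up in the same block when at least
``min_link`` sequencing fragments (a read plus its mate) observe alleles at
both. Within a block the relative orientation of each site is the majority
vote per linkage edge, propagated along a maximum spanning tree of the
fragment-linkage graph; an edge whose cis and trans support tie carries no
orientation and the block splits there. A second, longer-insert read set
can afterwards merge blocks that the first set could not bridge.

Only SNP het sites are phased; bases below quality 13 do not vote.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .formats import AlignedRead
from .variants import HetSite

MIN_VOTE_QUALITY = 13


@dataclass
class PhasedBlock:
    """A maximal set of het sites with a determined relative haplotype
    assignment; hap_a/hap_b give each haplotype's base per site."""

    block_id: str
    locus_id: str
    positions: list[int]
    hap_a: str
    hap_b: str
    support: dict[tuple[int, int], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if not (len(self.positions) == len(self.hap_a) == len(self.hap_b)):
            raise ValueError("haplotype strings must cover every position")
        for a, b in zip(self.hap_a, self.hap_b):
            if a == b:
                raise ValueError("haplotypes agree at a supposedly het site")

    @property
    def span(self) -> tuple[int, int]:
        return self.positions[0], self.positions[-1]

    def alleles_at(self, position: int) -> tuple[str, str]:
        i = self.positions.index(position)
        return self.hap_a[i], self.hap_b[i]


@dataclass
class Cooccurrence:
    """Fragment co-observations of base combinations at het-site pairs."""

    sites: list[HetSite]
    pair_counts: dict[tuple[int, int], Counter]
    noise: Counter = field(default_factory=Counter)

    def cis_trans(self, i: int, j: int) -> tuple[int, int]:
        """Concordant/discordant fragment counts for sites i < j, where
        cis pairs site i's base1 with site j's base1."""
        c = self.pair_counts.get((i, j), Counter())
        si, sj = self.sites[i], self.sites[j]
        cis = c[(si.base1, sj.base1)] + c[(si.base2, sj.base2)]
        trans = c[(si.base1, sj.base2)] + c[(si.base2, sj.base1)]
        return cis, trans


def fragment_observations(
    het_sites: list[HetSite], reads: list[AlignedRead]
) -> dict[str, dict[int, str]]:
    """Per fragment (read + mate), the allele observed at each het site.

    Bases that match neither allele of a site, or fall below the voting
    quality, are excluded (returned under the special site index -1 count
    only via build_cooccurrence's noise tally).
    """
    positions = [s.position for s in het_sites]
    alleles = [{s.base1, s.base2} for s in het_sites]
    obs: dict[str, dict[int, str]] = defaultdict(dict)
    noisy: list[tuple[str, int]] = []
    for read in reads:
        for rs, qs, n in read.aligned_blocks():
            import bisect

            lo = bisect.bisect_left(positions, rs)
            hi = bisect.bisect_left(positions, rs + n)
            for k in range(lo, hi):
                base = read.sequence[qs + positions[k] - rs]
                qual = int(read.qualities[qs + positions[k] - rs])
                if qual < MIN_VOTE_QUALITY:
                    continue
                if base not in alleles[k]:
                    noisy.append((read.pair_id, k))
                    continue
                prev = obs[read.pair_id].get(k)
                if prev is not None and prev != base:
                    # mates disagree at the same site: drop the vote
                    del obs[read.pair_id][k]
                    noisy.append((read.pair_id, k))
                else:
                    obs[read.pair_id][k] = base
    obs["__noise__"] = {i: "" for _, i in noisy}  # marker, consumed below
    return obs


def build_cooccurrence(
    het_sites: list[HetSite], reads: list[AlignedRead]
) -> Cooccurrence:
    """Tally, per pair of het sites, the base combinations co-observed on
    single fragments. The fragment (read pair) is the counting unit."""
    het_sites = sorted(het_sites, key=lambda s: s.position)
    obs = fragment_observations(het_sites, reads)
    noise_marks = obs.pop("__noise__", {})
    pair_counts: dict[tuple[int, int], Counter] = defaultdict(Counter)
    for frag, sites in obs.items():
        idx = sorted(sites)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                pair_counts[(i, j)][(sites[i], sites[j])] += 1
    noise = Counter({i: 1 for i in noise_marks})
    return Cooccurrence(sites=het_sites, pair_counts=dict(pair_counts), noise=noise)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def phase_locus(
    het_sites: list[HetSite],
    cooc: Cooccurrence,
    min_link: int = 1,
    locus_id: str | None = None,
) -> list[PhasedBlock]:
    """Partition het sites into phased blocks.

    Connected components of the linkage graph (edges with at least
    ``min_link`` informative fragments and a cis/trans majority) become
    blocks; orientations propagate along a maximum spanning tree weighted
    by |cis - trans|. Isolated sites become singleton blocks.
    """
    sites = cooc.sites
    n = len(sites)
    if n == 0:
        return []
    locus_id = locus_id or sites[0].locus_id
    edges = []  # (weight, i, j, flip)
    for (i, j) in sorted(cooc.pair_counts):
        cis, trans = cooc.cis_trans(i, j)
        if cis + trans < min_link or cis == trans:
            continue  # unlinked, or a tie: carries no orientation
        edges.append((abs(cis - trans), i, j, trans > cis))
    edges.sort(key=lambda e: (-e[0], e[1], e[2]))
    uf = _UnionFind(n)
    tree = defaultdict(list)
    for w, i, j, flip in edges:
        if uf.union(i, j):
            tree[i].append((j, flip))
            tree[j].append((i, flip))
    orientation = [0] * n
    seen = [False] * n
    for root in range(n):
        if seen[root]:
            continue
        stack = [root]
        seen[root] = True
        while stack:
            u = stack.pop()
            for v, flip in tree[u]:
                if not seen[v]:
                    orientation[v] = orientation[u] ^ int(flip)
                    seen[v] = True
                    stack.append(v)
    comps: dict[int, list[int]] = defaultdict(list)
    for k in range(n):
        comps[uf.find(k)].append(k)
    blocks = []
    for b, members in enumerate(sorted(comps.values(), key=lambda m: m[0])):
        members.sort()
        hap_a = "".join(
            (sites[k].base1, sites[k].base2)[orientation[k]] for k in members
        )
        hap_b = "".join(
            (sites[k].base2, sites[k].base1)[orientation[k]] for k in members
        )
        support = {}
        for a, bnext in zip(members, members[1:]):
            support[(sites[a].position, sites[bnext].position)] = cooc.cis_trans(a, bnext)
        blocks.append(
            PhasedBlock(
                block_id=f"{locus_id}:b{b}",
                locus_id=locus_id,
                positions=[sites[k].position for k in members],
                hap_a=hap_a,
                hap_b=hap_b,
                support=support,
            )
        )
    return blocks


def merge_blocks(
    blocks: list[PhasedBlock],
    second_reads: list[AlignedRead],
    min_link: int = 1,
    min_conflict_frac: float = 0.2,
) -> tuple[list[PhasedBlock], list[dict]]:
    """Join blocks using linkage evidence from a second read set.

    Two blocks merge when the second read set phases at least one site of
    each with ``min_link`` or more fragments agreeing on an orientation.
    Linkage is contradictory — and the merge rejected, with a report —
    when the minority orientation is supported strictly above ``min_link``
    AND carries at least ``min_conflict_frac`` of the linking fragments
    (below that it is indistinguishable from sequencing error, the same
    minor-fraction logic the genotyper uses). An orientation that conflicts
    with merges already accepted is likewise rejected. Returns
    (merged blocks, rejections).
    """
    if len(blocks) <= 1:
        return list(blocks), []
    locus_id = blocks[0].locus_id
    het_sites = []
    site_block = {}
    for bi, blk in enumerate(blocks):
        for pos, a, b in zip(blk.positions, blk.hap_a, blk.hap_b):
            het_sites.append(
                HetSite(locus_id, pos, min(a, b), max(a, b), 0, 0)
            )
            site_block[pos] = bi
    het_sites.sort(key=lambda s: s.position)
    cooc = build_cooccurrence(het_sites, second_reads)
    # per block pair: votes for keeping vs flipping relative orientation
    votes: dict[tuple[int, int], list[int]] = defaultdict(lambda: [0, 0])
    for (i, j), counter in cooc.pair_counts.items():
        si, sj = cooc.sites[i], cooc.sites[j]
        bi, bj = site_block[si.position], site_block[sj.position]
        if bi == bj:
            continue
        ai = blocks[bi].alleles_at(si.position)
        aj = blocks[bj].alleles_at(sj.position)
        same = counter[(ai[0], aj[0])] + counter[(ai[1], aj[1])]
        flip = counter[(ai[0], aj[1])] + counter[(ai[1], aj[0])]
        key = (min(bi, bj), max(bi, bj))
        if (bi < bj):
            votes[key][0] += same
            votes[key][1] += flip
        else:
            votes[key][0] += same
            votes[key][1] += flip
    uf = _UnionFind(len(blocks))
    rel = [0] * len(blocks)  # orientation relative to component root

    def root_and_parity(x: int) -> tuple[int, int]:
        p = 0
        while uf.parent[x] != x:
            p ^= rel[x]
            x = uf.parent[x]
        return x, p

    rejections = []
    for (bi, bj) in sorted(votes, key=lambda k: (min(votes[k]) - max(votes[k]), k)):
        same, flip = votes[(bi, bj)]
        if min(same, flip) > min_link and min(same, flip) >= min_conflict_frac * (same + flip):
            rejections.append(
                {"blocks": (blocks[bi].block_id, blocks[bj].block_id),
                 "reason": "contradictory linkage", "same": same, "flip": flip}
            )
            continue
        if max(same, flip) < min_link:
            continue
        want_flip = int(flip > same)
        ri, pi = root_and_parity(bi)
        rj, pj = root_and_parity(bj)
        if ri == rj:
            if pi ^ pj != want_flip:
                rejections.append(
                    {"blocks": (blocks[bi].block_id, blocks[bj].block_id),
                     "reason": "inconsistent with accepted merges",
                     "same": same, "flip": flip}
                )
            continue
        uf.parent[rj] = ri
        rel[rj] = pi ^ pj ^ want_flip
    groups: dict[int, list[int]] = defaultdict(list)
    parity: dict[int, int] = {}
    for b in range(len(blocks)):
        r, p = root_and_parity(b)
        groups[r].append(b)
        parity[b] = p
    merged = []
    for k, members in enumerate(sorted(groups.values(), key=lambda m: blocks[m[0]].positions[0])):
        entries = []
        for b in members:
            blk = blocks[b]
            for pos, a, hb in zip(blk.positions, blk.hap_a, blk.hap_b):
                entries.append((pos, (a, hb) if parity[b] == 0 else (hb, a)))
        entries.sort()
        support = {}
        for b in members:
            support.update(blocks[b].support)
        merged.append(
            PhasedBlock(
                block_id=f"{locus_id}:m{k}",
                locus_id=locus_id,
                positions=[p for p, _ in entries],
                hap_a="".join(a for _, (a, _) in entries),
                hap_b="".join(b for _, (_, b) in entries),
                support=support,
            )
        )
    return merged, rejections


def extract_alleles(block: PhasedBlock, consensus: str) -> tuple[str, str]:
    """The two full-length allele sequences implied by one block: the
    consensus with each haplotype's bases substituted at the block's sites."""
    if block.positions and block.positions[-1] >= len(consensus):
        raise ValueError("block positions exceed consensus length")
    a1, a2 = list(consensus), list(consensus)
    for pos, a, b in zip(block.positions, block.hap_a, block.hap_b):
        a1[pos] = a
        a2[pos] = b
    return "".join(a1), "".join(a2)
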