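"""Site calls from aligned reads: pileup, genotyping, variation summaries.

Calling follows the usual short-read conventions: a site needs a minimum
depth (default 10) and a Phred-scaled site quality (default 10) to be
called; a site is heterozygous when exactly two alleles each carry at
least ``min_allele_frac`` of the depth. Site quality is the Phred-scaled
binomial tail probability of the minor-allele count arising from
sequencing error alone. Indel alleles are taken from the pileup (keyed by
their edit string, anchored VCF-style at the base before the event).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .formats import AlignedRead, SequenceRecord, VcfVariant

BASES = "ACGT"
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i


@dataclass
class Pileup:
    """Per-position allele counts over one reference sequence."""

    locus_id: str
    length: int
    counts: np.ndarray                      # (length, 4) base observations
    indels: dict[int, Counter] = field(default_factory=dict)
    noise: np.ndarray | None = None         # bases dropped by the quality floor

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class SiteCall:
    locus_id: str
    position: int
    depth: int
    allele_counts: dict[str, int]
    genotype: str  # hom_ref | het | hom_alt | multiallelic
    site_quality: float
    is_indel: bool = False

    @property
    def alleles(self) -> list[str]:
        return sorted(self.allele_counts, key=self.allele_counts.get, reverse=True)


@dataclass
class HetSite:
    locus_id: str
    position: int
    base1: str
    base2: str
    count1: int
    count2: int

    def __post_init__(self):
        if self.base1 == self.base2:
            raise ValueError("heterozygous site with identical alleles")


@dataclass
class CallResult:
    """Variant calls plus the callable span they were made over."""

    locus_id: str
    calls: list[SiteCall]
    callable_length: int

    @property
    def het_sites(self) -> list[HetSite]:
        out = []
        for c in self.calls:
            if c.genotype != "het" or c.is_indel:
                continue
            (b1, n1), (b2, n2) = Counter(c.allele_counts).most_common(2)
            out.append(HetSite(c.locus_id, c.position, b1, b2, n1, n2))
        return out


def pileup(
    reads: list[AlignedRead],
    reference: SequenceRecord,
    min_base_q: int = 13,
) -> Pileup:
    """Count base and indel observations per reference position.

    Bases below ``min_base_q`` and N bases never count as evidence. Reads
    overhanging the reference end are clipped with a warning.
    """
    L = len(reference.sequence)
    pos_chunks, code_chunks = [], []
    indels: dict[int, Counter] = {}
    clipped = 0
    for read in reads:
        if read.locus_id != reference.id:
            continue
        seq_codes = _LUT[np.frombuffer(read.sequence.encode(), dtype=np.uint8)]
        quals = np.asarray(read.qualities, dtype=np.int16)
        for rs, qs, n in read.aligned_blocks():
            take = n
            if rs + n > L:
                take = max(0, L - rs)
                clipped += 1
            if take <= 0:
                continue
            codes = seq_codes[qs:qs + take]
            q = quals[qs:qs + take]
            keep = (codes < 4) & (q >= min_base_q)
            if keep.all():
                pos_chunks.append(np.arange(rs, rs + take))
                code_chunks.append(codes)
            else:
                idx = np.flatnonzero(keep)
                pos_chunks.append(rs + idx)
                code_chunks.append(codes[idx])
        for anchor, edit in read.indel_events():
            if 0 <= anchor < L:
                indels.setdefault(anchor, Counter())[edit] += 1
    if clipped:
        warnings.warn(f"{reference.id}: clipped {clipped} read blocks at reference end")
    counts = np.zeros((L, 4), dtype=np.int32)
    if pos_chunks:
        allpos = np.concatenate(pos_chunks)
        allcode = np.concatenate(code_chunks).astype(np.int64)
        np.add.at(counts, (allpos, allcode), 1)
    return Pileup(locus_id=reference.id, length=L, counts=counts, indels=indels)


def call_sites(
    pile: Pileup,
    reference: SequenceRecord,
    min_cov: int = 10,
    min_qual: float = 10.0,
    min_allele_frac: float = 0.2,
    error_rate: float = 0.001,
) -> CallResult:
    """Genotype every sufficiently covered position; return variant calls.

    Positions below ``min_cov`` are uncallable; variant sites whose quality
    is below ``min_qual`` are dropped. Only non-reference genotypes are
    materialized (hom_ref is implied for every other callable position).
    """
    depth = pile.depth
    callable_mask = depth >= min_cov
    callable_length = int(callable_mask.sum())
    ref_codes = _LUT[np.frombuffer(reference.sequence.encode(), dtype=np.uint8)]
    counts = pile.counts
    with np.errstate(invalid="ignore", divide="ignore"):
        fracs = counts / np.maximum(depth, 1)[:, None]
    passing = (fracs >= min_allele_frac) & (counts > 0)
    n_passing = passing.sum(axis=1)
    ref_passing = np.take_along_axis(
        passing, np.minimum(ref_codes, 3)[:, None].astype(np.int64), axis=1
    )[:, 0]
    # candidate SNP sites: callable, and not "one passing allele == ref"
    snp_candidates = np.flatnonzero(
        callable_mask & ((n_passing > 1) | ((n_passing == 1) & ~ref_passing))
    )
    calls: list[SiteCall] = []
    err = max(error_rate, 1e-6)
    for p in snp_candidates:
        p = int(p)
        cc = counts[p]
        d = int(depth[p])
        alleles = {BASES[b]: int(cc[b]) for b in range(4) if passing[p, b]}
        order = sorted(alleles, key=alleles.get, reverse=True)
        if len(order) >= 3:
            genotype = "multiallelic"
            minor = alleles[order[1]]
        elif len(order) == 2:
            genotype = "het"
            minor = alleles[order[1]]
        else:
            genotype = "hom_alt"
            minor = max(alleles[order[0]], 1)  # confidence in the alt allele itself
        qual = _phred_binom(minor, d, err)
        if qual < min_qual:
            continue
        all_counts = {BASES[b]: int(cc[b]) for b in range(4) if cc[b] > 0}
        calls.append(
            SiteCall(
                locus_id=pile.locus_id,
                position=p,
                depth=d,
                allele_counts=all_counts,
                genotype=genotype,
                site_quality=qual,
            )
        )
    # indel sites
    for p, edits in sorted(pile.indels.items()):
        d = int(depth[p])
        if d < min_cov:
            continue
        passing_edits = {e: n for e, n in edits.items() if n / d >= min_allele_frac}
        if not passing_edits:
            continue
        total_edit = sum(passing_edits.values())
        ref_support = d - sum(edits.values())
        if len(passing_edits) > 1:
            genotype = "multiallelic"
        elif ref_support / d >= min_allele_frac:
            genotype = "het"
        else:
            genotype = "hom_alt"
        qual = _phred_binom(min(total_edit, max(ref_support, 1)), d, err)
        if qual < min_qual:
            continue
        allele_counts = dict(passing_edits)
        allele_counts["."] = ref_support
        calls.append(
            SiteCall(
                locus_id=pile.locus_id,
                position=int(p),
                depth=d,
                allele_counts=allele_counts,
                genotype=genotype,
                site_quality=qual,
                is_indel=True,
            )
        )
    calls.sort(key=lambda c: c.position)
    return CallResult(locus_id=pile.locus_id, calls=calls, callable_length=callable_length)


def _phred_binom(k: int, n: int, err: float) -> float:
    """Phred-scaled P(X >= k) for X ~ Binomial(n, err); capped at 999."""
    if k <= 0:
        return 0.0
    pval = stats.binom.sf(k - 1, n, err)
    if pval <= 0:
        return 999.0
    return float(min(999.0, -10.0 * np.log10(pval)))


def summarize_variation(result: CallResult | list[CallResult]) -> dict:
    """SNP/indel rates over the callable span, plus the clonality check.

    snp_rate counts heterozygous SNP sites per callable base; the
    multiallelic count is reported because a clonal population should show
    essentially none.
    """
    results = result if isinstance(result, list) else [result]
    callable_length = sum(r.callable_length for r in results)
    if callable_length <= 0:
        raise ValueError("no callable positions")
    het_snp = het_indel = multi = 0
    for r in results:
        for c in r.calls:
            if c.genotype == "multiallelic":
                multi += 1
            elif c.is_indel and c.genotype == "het":
                het_indel += 1
            elif not c.is_indel and c.genotype == "het":
                het_snp += 1
    return {
        "snp_rate": het_snp / callable_length,
        "indel_rate": het_indel / callable_length,
        "het_count": het_snp + het_indel,
        "multiallelic_count": multi,
        "callable_length": callable_length,
    }


def calls_to_vcf_variants(
    result: CallResult, reference: SequenceRecord
) -> list[VcfVariant]:
    """Map SNP calls onto VCF records (indels are reported separately)."""
    variants = []
    for c in result.calls:
        if c.is_indel:
            continue
        ref_base = reference.sequence[c.position]
        alts = tuple(a for a in c.alleles if a != ref_base and a in BASES)
        if not alts:
            continue
        variants.append(
            VcfVariant(
                chrom=c.locus_id,
                pos=c.position,
                ref=ref_base,
                alts=alts,
                qual=round(c.site_quality, 1),
                info={"DP": c.depth},
            )
        )
    return variants
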