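"""End-to-end pipeline wiring: simulate, call, phase, compare, evaluate.

``run_reproduce_preset30`` executes the whole chain on the deterministic
30-locus preset: simulate RNA-like and genomic-like paired reads for both
lineages, call heterozygous sites (minimum coverage 10, quality 10), phase
the RNA evidence into blocks, merge blocks with the genomic linkage,
classify loci by cross-lineage allele sharing, and evaluate the observed
sharing fraction against genealogy hypotheses. All randomness flows from
one seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from . import alleles, genealogy, phasing, simulate, variants
from .formats import SequenceRecord


@dataclass
class VariantParams:
    min_cov: int = 10
    min_qual: float = 10.0
    min_allele_frac: float = 0.2
    min_base_q: int = 13
    error_rate: float = 0.001


@dataclass
class PhasingParams:
    min_link: int = 1
    max_blocks: int = 6


@dataclass
class GenealogyParams:
    reps: int = 1000
    somatic_rate: float = 0.13
    ancestral_het_rate: float = 0.01
    locus_length: int = 999
    condition_on_nonidentical: bool = True


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "."
    variants: VariantParams = field(default_factory=VariantParams)
    phasing: PhasingParams = field(default_factory=PhasingParams)
    genealogy: GenealogyParams = field(default_factory=GenealogyParams)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for name, value in data.items():
            f = known[name]
            if name in ("variants", "phasing", "genealogy"):
                sub = f.default_factory()  # type: ignore[misc]
                bad = set(value) - {g.name for g in fields(sub)}
                if bad:
                    raise ValueError(f"unknown config keys in {name}: {sorted(bad)}")
                kwargs[name] = type(sub)(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)


@dataclass
class LineageResult:
    lineage: str
    call_results: dict[str, variants.CallResult]
    blocks: dict[str, list[phasing.PhasedBlock]]
    blocks_before_merge: dict[str, int]
    consensus: dict[str, str]
    merge_rejections: list[dict]


def process_lineage(
    lineage: str,
    reference: list[SequenceRecord],
    rna_reads,
    genomic_reads,
    vp: VariantParams,
    pp: PhasingParams,
) -> LineageResult:
    """Call het sites from the pooled pileup, phase on RNA fragments, merge
    blocks with genomic linkage, and derive the lineage consensus."""
    by_locus_rna: dict[str, list] = {}
    by_locus_gen: dict[str, list] = {}
    for r in rna_reads:
        by_locus_rna.setdefault(r.locus_id, []).append(r)
    for r in genomic_reads:
        by_locus_gen.setdefault(r.locus_id, []).append(r)
    call_results, blocks, consensus = {}, {}, {}
    blocks_before = {}
    rejections: list[dict] = []
    for ref in reference:
        reads_rna = by_locus_rna.get(ref.id, [])
        reads_gen = by_locus_gen.get(ref.id, [])
        pile = variants.pileup(reads_rna + reads_gen, ref, min_base_q=vp.min_base_q)
        result = variants.call_sites(
            pile,
            ref,
            min_cov=vp.min_cov,
            min_qual=vp.min_qual,
            min_allele_frac=vp.min_allele_frac,
            error_rate=vp.error_rate,
        )
        call_results[ref.id] = result
        het = result.het_sites
        cooc = phasing.build_cooccurrence(het, reads_rna)
        rna_blocks = phasing.phase_locus(het, cooc, min_link=pp.min_link, locus_id=ref.id)
        blocks_before[ref.id] = len(rna_blocks)
        merged, rej = phasing.merge_blocks(rna_blocks, reads_gen, min_link=pp.min_link)
        rejections.extend(rej)
        blocks[ref.id] = merged
        cons = list(ref.sequence)
        for call in result.calls:
            if call.genotype == "hom_alt" and not call.is_indel:
                cons[call.position] = call.alleles[0]
        consensus[ref.id] = "".join(cons)
    return LineageResult(
        lineage=lineage,
        call_results=call_results,
        blocks=blocks,
        blocks_before_merge=blocks_before,
        consensus=consensus,
        merge_rejections=rejections,
    )


def compare_lineages(
    res_a: LineageResult,
    res_b: LineageResult,
    reference: list[SequenceRecord],
    max_blocks: int = 6,
    min_callable_frac: float = 0.5,
) -> list[alleles.LocusComparison]:
    """Per-locus comparisons, guarding against silent misclassification.

    A locus whose callable span falls below ``min_callable_frac`` of its
    length in either lineage is labelled indeterminate outright: with most
    sites uncallable, an apparent identity means nothing.
    """
    comparisons = []
    for ref in reference:
        frac = min(
            res_a.call_results[ref.id].callable_length,
            res_b.call_results[ref.id].callable_length,
        ) / len(ref.sequence)
        if frac < min_callable_frac:
            comparisons.append(
                alleles.LocusComparison(
                    locus_id=ref.id,
                    sharing_class="indeterminate",
                    alleles_a=None,
                    alleles_b=None,
                    min_unshared_distance=None,
                    note=f"only {frac:.0%} of the locus callable",
                )
            )
            continue
        comparisons.append(
            alleles.compare_locus(
                res_a.blocks[ref.id],
                res_b.blocks[ref.id],
                res_a.consensus[ref.id],
                res_b.consensus[ref.id],
                locus_id=ref.id,
                max_blocks=max_blocks,
            )
        )
    return comparisons


def detected_snps(res_a: LineageResult, res_b: LineageResult, locus_id: str) -> set[int]:
    """Polymorphic positions at a locus: het in either lineage, or differing
    between the lineage consensus sequences."""
    positions = {
        h.position
        for res in (res_a, res_b)
        for h in res.call_results[locus_id].het_sites
    }
    for p, (x, y) in enumerate(zip(res_a.consensus[locus_id], res_b.consensus[locus_id])):
        if x != y:
            positions.add(p)
    return positions


def run_reproduce_preset30(config: PipelineConfig | None = None) -> dict:
    """Full pipeline on the 30-locus preset; returns the summary report."""
    config = config or PipelineConfig()
    preset = simulate.make_preset30()
    results = {}
    for lineage in "AB":
        rna, gen = simulate.simulate_preset_reads(preset, lineage, config.seed)
        results[lineage] = process_lineage(
            lineage, preset.reference, rna, gen, config.variants, config.phasing
        )
    res_a, res_b = results["A"], results["B"]
    comparisons = compare_lineages(
        res_a, res_b, preset.reference, max_blocks=config.phasing.max_blocks
    )
    summary = alleles.classify_dataset(comparisons)
    snp_total = sum(
        len(detected_snps(res_a, res_b, ref.id)) for ref in preset.reference
    )
    block_total = sum(
        max(len(res_a.blocks[ref.id]), len(res_b.blocks[ref.id]))
        for ref in preset.reference
    )
    blocks_rna_only = sum(
        max(res_a.blocks_before_merge[ref.id], res_b.blocks_before_merge[ref.id])
        for ref in preset.reference
    )
    gp = config.genealogy
    hyp_results = [
        genealogy.expected_sharing(
            hyp,
            n_loci=len(preset.reference),
            reps=gp.reps,
            seed=config.seed + i + 1,
            ancestral_het_rate=gp.ancestral_het_rate,
            somatic_rate=gp.somatic_rate,
            locus_length=gp.locus_length,
            condition_on_nonidentical=gp.condition_on_nonidentical,
        )
        for i, hyp in enumerate(("parent_f1", "full_siblings", "unrelated"))
    ]
    verdicts = genealogy.evaluate_observed(summary["fraction_shared"], hyp_results)
    report = {
        "seed": config.seed,
        "n_loci": summary["n_loci"],
        "snp_total": snp_total,
        "block_total": block_total,
        "blocks_rna_only": blocks_rna_only,
        "fraction_shared": summary["fraction_shared"],
        "n_shared": summary["n_shared"],
        "n_four_distinct": summary["n_four_distinct"],
        "n_indeterminate": summary["n_indeterminate"],
        "total_min_unshared_substitutions": summary["total_min_unshared_substitutions"],
        "merge_rejections": len(res_a.merge_rejections) + len(res_b.merge_rejections),
        "genealogy": verdicts,
        "truth": preset.truth.to_dict(),
        "per_locus": [
            {
                "locus_id": c.locus_id,
                "class": c.sharing_class,
                "min_unshared_distance": c.min_unshared_distance,
                "blocks_a": c.n_blocks_a,
                "blocks_b": c.n_blocks_b,
            }
            for c in comparisons
        ],
    }
    return report
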