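# Methods

This note records the models, conventions, parameter choices, and known
limitations behind the package, in the order data flows through it.

## Coordinates and formats

All internal coordinates are 0-based, half-open. SAM and VCF are 1-based on
disk; conversion happens in `formats` (via pysam) and nowhere else, so
off-by-one risk is confined to one module. Reads are stored in reference
orientation (SAM stores SEQ that way already), making the phasing logic
strand-free. N bases never count as evidence for any allele.

## The two-lineage simulator

**Genealogies.** Founder haplotypes derive from one background sequence by
independent per-base mutation at half the ancestral heterozygosity rate
(default 0.01), so any diploid of two independent founders is heterozygous
at about that rate. Under *parent–F1*, lineage B receives one haplotype
copied from lineage A and one novel founder; under *full siblings*, each
lineage draws one haplotype from each of two founder parents, independently;
*unrelated* lineages are four independent founders; a *selfing* line redraws
both haplotypes from the current pair each generation. Somatic substitutions
are Poisson per locus per lineage (default rate 0.13 — the preset's 8 fixed
substitutions spread over 30 loci and 2 lineages) and land on exactly one
haplotype of one lineage; positions already variant are redrawn so sites
stay biallelic, matching the observation that multiallelic sites are
negligible in clonal populations. Heterozygous indels are planted only by
the genome-background simulator; the phased CDS loci carry SNPs only.

**Consensus model.** The ascertainment step of the real analysis examines
only loci whose assembly consensus differs between lineages. An assembler
emits one arbitrary allele per heterozygous site, so the simulated consensus
picks one haplotype per variant site at random. (Using "haplotype 1" as the
consensus instead would correlate the pick with parental origin under the
sibling genealogy and badly distort the conditional sharing fraction.)

**The `preset30` configuration.** A deterministic planted truth built from
an internal structure seed (locus lengths, site positions, and allele
patterns are one fixed object; only read noise follows the user seed): 30
CDS loci of 660–1,260 bp (random sense codons, total 29,001 bp) carrying
exactly 254 polymorphic sites distributed proportionally to length
(largest-remainder rounding, minimum 4 per locus). 24 loci share an
identical allele across lineages: the shared allele equals the locus
consensus, and the two second alleles alternate private substitutions.
6 loci carry four distinct alleles: the two "close" alleles differ by
planted somatic substitutions (1+1+1+2+1+2 = 8 in total) and each second
allele carries 7 private substitutions (~1% divergence; deeper divergence
is not representable within the 254-site budget at these locus sizes —
the qualitative structure, a close pair plus two divergent partners, is
what matters downstream). Seven loci contain an uncoverable joint: the
simulator rejects any fragment spanning it, and the flanking het sites sit
150 bp away on each side so their coverage stays deep; true block count is
therefore 30 + 7 = 37. Five further loci contain a 320 bp joint that
RNA-like fragments (2×75 bp, insert 180 ± 20) cannot span but genomic-like
fragments (2×150 bp, insert 450 ± 50) can, exercising the block-merge step.
Het sites keep ≥ 100 bp from locus ends (single-read edge coverage) and
adjacent spacings are capped so genomic fragments can link every non-joint
pair. Default coverages are 35x RNA-like and 80x genomic-like at base error
0.001 (Phred-scaled into read qualities).

**Read simulation.** Fragments are drawn uniformly, 50:50 from the two
haplotypes; both mates come from the same molecule (essential for phasing);
alignments are emitted by construction, so no mapper is involved. The
genome-background simulator plants het SNPs at 1% and het indels at 0.1%
(insertion/deletion 50:50, geometric lengths with mean 2, kept separated),
and reads from the edited haplotype carry correct I/D CIGARs.

## Variant calling

Pileup counts base observations per reference position (bases under quality
13 and Ns dropped) and indel alleles keyed by edit string, anchored
VCF-style at the base before the event. A position is callable at depth
≥ 10. Genotypes come from allele fractions: alleles at ≥ 20% of depth pass;
exactly two passing alleles is heterozygous, three or more multiallelic.
Site quality is the Phred-scaled binomial tail probability of the
minor-allele count arising from sequencing error alone, thresholded at 10.
The 20% minor-fraction floor suppresses error-driven het calls at high
depth; it is configurable. Rates are reported per callable base, so
low-coverage edges drop out of numerator and denominator together.
Filtering is applied after genotyping. Indel realignment is unnecessary
here because simulated alignments are true by construction; on real data a
realigned BAM should be supplied.

## Phasing

Fragments (read + mate, identified by pair id) vote on pairs of het sites
they co-observe; bases matching neither allele are tallied as noise, not
linkage, and mates disagreeing at a site cancel. Sites joined by at least
`min_link` fragments (default 1 — a single error-free fragment suffices,
as careful manual tracing would accept; raise it for noisy data) with a
cis/trans majority form a block; orientations propagate along a maximum
spanning tree weighted by |cis − trans|; a tied edge carries no orientation
and splits the block. On error-free fragments this equals the exhaustive
maximum-concordance assignment (property-tested against a brute-force
oracle up to 8 sites).

Merging with a second read set accepts the majority orientation between two
blocks. Linkage is *contradictory* — merge rejected and reported — only
when the minority orientation has support strictly above `min_link` **and**
at least 20% of the linking fragments: at 80x, one or two error-flipped
fragments would otherwise veto a merge backed by dozens, so the minority
fraction is judged the same way the genotyper judges a minor allele.
Orientations inconsistent with already-accepted merges are also rejected
and reported.

## Allele comparison

A locus is *shared_identical* when some full-length allele of lineage A
equals some allele of B nucleotide-for-nucleotide. Haplotype labels are
arbitrary per block, so with several blocks the comparison searches all
per-block assignments (identity must hold under a single assignment);
loci with more than 6 blocks per lineage are *indeterminate*, because with
enough independent blocks an apparent identical pair can always be
assembled. The pipeline additionally labels a locus indeterminate when less
than half of it reaches calling depth in either lineage — at degraded
coverage "no observed difference" must not masquerade as sharing. Loci with
no identical cross-lineage pair are *four_distinct*, annotated with the
minimum Hamming distance over cross-lineage allele pairs (for multi-block
loci this is a minimum over assignments, i.e. a lower bound). The dataset
sharing fraction is computed over determinate loci. Amino-acid reports
translate the reconstructed alleles (standard code) and count pairwise
differences within each lineage and between the unshared alleles; the
premature-stop scan reports in-frame stops before the terminal codon with
the truncated fraction of the protein.

The block count reported for a dataset is the per-locus maximum of the two
lineages' block counts, summed: uncoverable joints are properties of the
locus, so both lineages split at the same places and the maximum is the
natural per-CDS count.

## Genealogy evaluation

`expected_sharing` simulates replicate datasets (site-level fast path of the
same generator) and records the fraction of loci sharing an allele,
optionally conditioned on non-identical consensus; an observed fraction is
judged by whether it falls inside the central 95% replicate interval, with
its replicate quantile reported. No posterior probabilities are claimed —
the check is deliberately an interval test. At 30 loci with somatic rate
0.13, an observed 0.80 is consistent with both parent–F1 (replicate mean
≈ 0.88) and full siblings (≈ 0.69) and inconsistent with unrelated
lineages; the sharing fraction alone cannot separate the first two at this
sample size, and the package reports exactly that. Selfing is addressed
analytically (h₀·2⁻ᵍ) and by simulation.

## Divergence (NG86) and collinearity

Synonymous sites per codon are the fraction of the nine single-base changes
that preserve the amino acid; changes creating a stop codon count as
nonsynonymous, which keeps S + N = 3 × codon count exactly. Codons
differing at 2–3 positions average difference counts over all orderings of
the changes, excluding pathways through stop codons (all pathways used if
every one is blocked). Proportions are Jukes–Cantor corrected,
d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 marks the estimate saturated. Pairs with
dS = 0, dN = 0, or dS/dN ≥ 2 are excluded from summaries. Both the mean of
per-pair ratios and the ratio of mean rates are reported: at a handful of
synonymous events per gene the former is noticeably Jensen-inflated under
Poisson event counts. The pair simulator therefore defaults to expected
substitution counts with stochastic rounding (unbiased mean, both summary
statistics recover the configured truth); a Poisson mode is available. The
implementation agrees with an independent library implementation
(Bio.codonalign) to 4 decimals on random pairs, and single-step
classifications are tested exhaustively over all sense-codon changes.

Collinear chaining condenses tandem duplicates (anchors sharing a gene
index), then repeatedly extracts the longest run of anchors monotone in
both genomes (either orientation) with at most 20 intervening genes between
consecutive anchors on each genome, keeping chains of at least 5 pairs.
Ties break toward the smaller start index for determinism.

## Scaffold filters

Boundary semantics follow the wording of each rule: GC *deviation* is
strict (< 30% or > 35%); the endosymbiont GC criterion is inclusive
(≤ 30%). Endosymbiont classification requires jointly: no eukaryotic gene,
GC ≤ 30%, heterozygosity below 0.5 sites/kb, and coverage outside
[0.5×, 2×] of the expected 80x ("significantly below ... or significantly
higher" has no stated test; the band is a documented, configurable choice).
Any eukaryotic gene forces *host*, unconditionally. Redundancy removes a
scaffold enveloped by a strictly larger one at ≥ 98% identity over ≥ 80% of
its length (stable under containment chains); overlap joins require ≥ 1 kb
at ≥ 10x and ≥ 99% identity with every mismatch het-supported and no
conflicting alignment; the size cutoff keeps scaffolds ≥ 2 kb. Taxon labels
on genes and alignment summaries are inputs: homology search is out of
scope, and the provided exact-substring matcher exists for synthetic
fixtures only.

## Problem sizes, tolerances, determinism

The shipped analyses use: the 30-locus preset at 35x + 80x (exact recovery
of all planted quantities, verified across many seeds); 2,000 pairs of 300
codons for divergence (recovers dS 0.024 and dN/dS 0.37 within ~2%); a 1 Mb
background at 40x (rates within ~2% of planted 1%/0.1%). All randomness
flows from a single seed through numpy Generators; the preset's *structure*
is fixed by an internal constant so the planted truth does not vary with
the user's seed.

## What the synthetic data does and does not emulate

It emulates: diploid clonal lineages with realistic heterozygosity and
somatic fixation; two library types with different insert-length reach;
uniform i.i.d. sequencing errors with matching base qualities; coverage
gaps; planted indels with exact alignments. It does not emulate: mapping
ambiguity or alignment error (alignments are true by construction), quality
decay along reads, GC or coverage bias, PCR duplicates, structural
variants, paralogy, or recombination (lineages are clonal by premise).
Passing tests therefore demonstrate the correctness of the analysis logic
under its stated assumptions, not robustness to mapping artifacts — on real
data the upstream mapper and duplicate handling matter.

## Known limitations

- Phasing is majority-vote on the fragment graph, not MEC-optimal; for the
  coverage regimes here they coincide (tested), but adversarial error
  patterns could differ.
- The multi-block sharing test loses specificity as block count grows; the
  max-blocks guard (default 6) is a blunt but explicit control.
- NG86 assumes equal base frequencies and no transition/transversion bias
  (Jukes–Cantor); at dS ≈ 0.02 the bias relative to ML codon models is well
  inside the reported tolerances, but at high divergence a codon-model
  estimator should be preferred.
- The genealogy test is an interval check under an explicit simulator, not
  model selection; hypotheses with overlapping predictions (parent–F1 vs
  full siblings at 30 loci) stay unresolved by design.
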