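"""Assembly cleanup: GC deviants, endosymbiont scaffolds, redundancy, size.

Builds a small synthetic assembly mixing host scaffolds (GC ~33%, ~80x
coverage, heterozygous) with rickettsial-endosymbiont-like scaffolds
(GC ~27%, ~15x, no haplotypic variation), plus a redundant fragment, and
runs the stepwise classification rules.
"""

import numpy as np

from clonelineage.scaffolds import (
    ScaffoldRecord,
    apply_size_cutoff,
    classify_endosymbiont,
    exact_envelopment_matches,
    find_redundant,
    flag_gc_deviant,
)

rng = np.random.default_rng(0)


def _seq(length, gc):
    pool = "GC" if rng.random() < gc else "AT"
    return "".join(
        rng.choice(list("GC" if rng.random() < gc else "AT")) for _ in range(length)
    )


host = [
    ScaffoldRecord(id=f"host_{i}", sequence=_seq(6000, 0.33), mean_coverage=80,
                   het_density=10, genes=[(f"g{i}", "eukaryotic")])
    for i in range(4)
]
endo = [
    ScaffoldRecord(id=f"endo_{i}", sequence=_seq(5000, 0.27), mean_coverage=15,
                   het_density=0, genes=[(f"b{i}", "bacterial")])
    for i in range(2)
]
fragment = ScaffoldRecord(id="fragment", sequence=host[0].sequence[:3000],
                          mean_coverage=80, het_density=10)
tiny = ScaffoldRecord(id="tiny", sequence=_seq(1500, 0.33), mean_coverage=80)

assembly = host + endo + [fragment, tiny]
redundant = set(find_redundant(assembly, exact_envelopment_matches(assembly)))
kept = {s.id for s in apply_size_cutoff(assembly, min_len=2000)}

print(f"{'scaffold':>10} {'GC':>6} {'deviant':>8} {'class':>13} "
      f"{'redundant':>10} {'<2kb':>5}")
for s in assembly:
    print(f"{s.id:>10} {s.gc_fraction:6.3f} {str(flag_gc_deviant(s)):>8} "
          f"{classify_endosymbiont(s):>13} {str(s.id in redundant):>10} "
          f"{str(s.id not in kept):>5}")
# Endosymbiont scaffolds satisfy all four criteria (no eukaryotic gene,
# GC <= 30%, no haplotypic variation, coverage far from the expected 80x);
# the enveloped fragment is removed as redundant; sub-2kb scaffolds are cut.
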