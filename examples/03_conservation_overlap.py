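"""Cross-species conservation of alternative splicing over 1:1 orthologs.

Given a 1:1 ortholog map and the set of alternatively spliced genes in
each species, count ortholog pairs where one or both members are
alternatively spliced, and merge candidate sets from two annotation
sources with inclusion-exclusion bookkeeping.
"""

from ctsai import (
    GeneSet,
    OrthologMap,
    as_conservation_overlap,
    merge_candidate_sets,
)

orthologs = OrthologMap(tuple((f"vA{i:03d}", f"cB{i:03d}") for i in range(100)))
as_species_a = GeneSet("speciesA_AS", frozenset(f"vA{i:03d}" for i in range(0, 40)))
as_species_b = GeneSet("speciesB_AS", frozenset(f"cB{i:03d}" for i in range(25, 55)))

in_a, in_b, both = as_conservation_overlap(orthologs, as_species_a, as_species_b)
print(f"ortholog pairs with AS in species A: {in_a}")
print(f"ortholog pairs with AS in species B: {in_b}")
print(f"pairs with AS in both species:       {both}")
# 'both' <= min(in_a, in_b); a small 'both' relative to the single-species
# counts indicates little conservation of alternative splicing.

a = GeneSet("denovo", frozenset(f"g{i}" for i in range(60)))
b = GeneSet("reference", frozenset(f"g{i}" for i in range(47, 67)))
report, merged, provenance = merge_candidate_sets(a, b)
print(f"\nmerge: |A|={report.size_a} |B|={report.size_b} "
      f"shared={report.intersection} union={report.union} "
      f"unique to B={report.unique_b}")
# The union is the combined candidate list; provenance tags each gene as
# a-only / b-only / both for downstream reporting.
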