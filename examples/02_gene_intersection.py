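"""Multi-source disease gene union and drug-disease intersection.

Builds five synthetic disease-gene sources and a compound-target map with a
planted 150-gene overlap, unions the sources, and intersects with the drug
targets.  The Venn region counts summarise how the five sources share genes.
"""

from herbnet import SynthConfig, gen_drug_disease, intersect_drug_disease, union_sources, venn_counts

target_map, sources, truth = gen_drug_disease(SynthConfig(seed=42))
union, per_source, pairwise = union_sources(sources, label="disease")
inter = intersect_drug_disease(target_map.all_targets(), union)

print("per-source sizes:", per_source)
print(f"disease union: {len(union)} genes")
print(f"drug targets:  {len(target_map.all_targets())} genes")
print(f"intersection:  {len(inter)} genes (planted overlap was {len(truth['planted_overlap'])})")
counts = venn_counts(sources)
print(f"genes present in all five sources: {counts[(1, 1, 1, 1, 1)]}")
# The intersection tracks the planted overlap: a gene can only drop out when
# no disease source happened to sample it.
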