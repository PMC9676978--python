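"""Median-centrality core extraction from a scored PPI network.

Generates a synthetic PPI with a planted 20-node dense core and an 80-node
sparse periphery, keeps edges with confidence >= 0.9, computes the six
screening centralities (Degree, Betweenness, Closeness, Eigenvector, LAC,
Network) and retains the nodes strictly above the median on all of them.
"""

from herbnet import ScreenConfig, SynthConfig, build_network, compute_centralities, gen_ppi, screen_core

edges, planted_core = gen_ppi(SynthConfig(seed=7))
net = build_network(edges, min_score=0.9)
print(f"network after 0.9 score cut: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges")

table = compute_centralities(net)
print("medians:", {m: round(float(table[m].median()), 3) for m in table.columns})

result = screen_core(net, ScreenConfig(rounds=1))
retained = set(result.retained)
tp = retained & set(planted_core)
print(f"retained core: {len(retained)} nodes; {len(tp)} of them planted "
      f"(precision {len(tp) / len(retained):.0%})")
# High precision means the median rule is pulling out the planted dense
# module rather than the preferential-attachment periphery.
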