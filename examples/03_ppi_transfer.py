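"""Homology-transferred PPI network and condition-specific hub calling.

Generates an ortholog map (one reference gene per protein, homology drawn
around 67%) and a STRING-like interaction table, filters interactions on
evidence scores (database > 0.15 OR experimental > 0.35), transfers them to
protein space, extracts per-condition subnetworks from presence calls, and
calls hubs as nodes above the network mean in both betweenness and centroid
centrality.
"""

import spcnet
from spcnet.conditions import BASE_CONDITIONS

counts, meta, truth = spcnet.generate_spc_dataset(spcnet.default_config(seed=1))
orthologs = spcnet.generate_ortholog_map(list(counts.index), mean_homology=67.0, seed=1)
interactions = spcnet.generate_interaction_table(truth, seed=1, ortholog_map=orthologs)

print(f"mean homology of the ortholog map: {spcnet.mean_homology(orthologs):.1f}%")
filtered = spcnet.filter_interactions(interactions)
print(f"interactions: {len(interactions)} rows, {len(filtered)} pass the score filter")

ppi = spcnet.transfer_interactions(filtered, orthologs, proteome=list(counts.index))
connected = spcnet.ppinet.drop_isolated_nodes(ppi)
print(f"transferred PPI network: {connected.number_of_nodes()} connected nodes, "
      f"{ppi.number_of_edges()} edges")

hub_sets = {}
for cond in BASE_CONDITIONS:
    present = spcnet.condition_presence(counts, meta, cond)
    sub = spcnet.extract_condition_subnetwork(ppi, present, drop_isolated=True)
    ct = spcnet.centrality_table(sub)
    hub_sets[cond] = spcnet.call_hubs(ct, mode="ppi")
    print(f"{cond}: {sub.number_of_nodes()} nodes, {sub.number_of_edges()} edges, "
          f"{len(hub_sets[cond])} hubs")

for factor in ("Fe", "Mo"):
    specific = spcnet.condition_specific_hubs(hub_sets, factor)
    for level, hubs in specific.items():
        print(f"hubs specific to {level}: {len(hubs)}")
# a level-specific hub is a hub in both networks of that factor level and in
# neither network of the opposite level
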