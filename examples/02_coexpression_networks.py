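"""Build the four grouping co-expression networks from synthetic counts.

Each network pools the samples of one condition grouping (e.g. Fe starvation
= both conditions grown without Fe), keeps proteins identified in >=51% of
those samples, and connects pairs with |Spearman rho| > 0.7 at p < 0.01.
Degree hubs are nodes whose degree exceeds the network mean.
"""

import spcnet

counts, meta, truth = spcnet.generate_spc_dataset(spcnet.default_config(seed=1))
networks = spcnet.build_grouping_networks(counts, meta)

for grouping, net in networks.items():
    ct = spcnet.centrality_table(net)
    hubs = spcnet.call_hubs(ct, mode="coexpression")
    n_neg = sum(1 for _, _, d in net.edges(data=True) if d["sign"] == "negative")
    print(f"{grouping}: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges ({n_neg} negative), "
          f"mean degree {ct.mean_degree:.1f}, {len(hubs)} degree hubs")

# the ego network of a planted anchor: the hub plus everything co-expressed
# with it in its active grouping
anchor = sorted(truth.anchors["Mo_starvation"])[0]
ego = spcnet.ego_network(networks["Mo_starvation"], anchor)
print(f"\nego network of {anchor} under Mo starvation: "
      f"{ego.number_of_nodes() - 1} partners, {ego.number_of_edges()} edges")
# a high partner count specific to one grouping is the signature the
# differential-correlation analysis looks for
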