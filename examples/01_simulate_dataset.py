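"""Generate a synthetic spectral-count dataset with planted structure.

Builds the default 300-protein, 27-sample design (6/8/6/7 replicates over
the four Fe/Mo base conditions), then summarizes what was planted: four
co-expression modules (one per condition grouping, each with a high-loading
anchor protein), differentially expressed proteins, and detection dropout.
"""

import spcnet
from spcnet.conditions import grouping_sizes

counts, meta, truth = spcnet.generate_spc_dataset(spcnet.default_config(seed=1))

print(f"count matrix: {counts.shape[0]} proteins x {counts.shape[1]} samples")
print(f"fraction of zero counts (dropout + low abundance): "
      f"{(counts.to_numpy() == 0).mean():.2f}")
print("samples per grouping:", grouping_sizes(meta))

for grouping, hubs in truth.planted_hubs.items():
    anchor = ", ".join(sorted(truth.anchors[grouping]))
    print(f"{grouping}: {len(hubs)} planted-module proteins (anchor {anchor})")
print(f"differentially expressed proteins: {len(truth.de_proteins)} "
      f"(log2 shift applied in one base condition each)")

kept = spcnet.prevalence_filter(counts)
print(f"proteins identified in >=51% of all samples: {len(kept)} of {len(counts)}")
# Most background proteins are low-abundance and drop below the prevalence
# threshold; the planted modules are abundant enough to survive it.
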