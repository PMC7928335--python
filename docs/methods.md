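# Methods

## Study design and condition groupings

The analysis targets a 2×2 nutritional design: Fe and Mo, each sufficient or
starved, giving base conditions +Mo+Fe, +Mo−Fe, −Mo+Fe, −Mo−Fe. Co-expression
analysis pools conditions into four *groupings*, one per factor level:
Fe sufficiency = {+Mo+Fe, −Mo+Fe}, Fe starvation = {+Mo−Fe, −Mo−Fe},
Mo sufficiency = {+Mo+Fe, +Mo−Fe}, Mo starvation = {−Mo+Fe, −Mo−Fe}.
Every sample belongs to exactly two groupings (one per factor), so any two
non-complementary groupings share the samples of one base condition. This
overlap is a structural property of the design and the main source of
cross-grouping leakage that both the pipeline and the generator must reckon
with (see below).

The default replicate allocation 6/8/6/7 over the four base conditions is
the unique non-negative integer solution of the pooled grouping sizes
(+Fe 12, +Mo 14, −Fe 15, −Mo 13) used throughout the recovery properties.

## Preprocessing

* **Detection.** A protein is *identified* in a sample iff its spectral
  count is positive. SpC data carry no explicit missingness flag, so zero is
  treated as "not identified" for presence/prevalence purposes but as an
  observed zero abundance for correlation (zeros are ranked, not dropped).
* **Normalization** scales each protein row to [0, 100] with the row maximum
  at 100. It is affine per protein, hence idempotent and rank-preserving;
  the co-expression branch is therefore provably invariant to it (asserted
  in the tests by direct edge-set comparison), and the DE branch uses it
  only for scale-free reporting.
* **Prevalence filter**: proteins identified in ≥ 51% of the considered
  samples, the boundary inclusive — 7/13 (53.8%) passes, 7/14 (exactly 50%)
  does not.
* **Differential expression** is the univariate one-way fixed-effects F
  ratio across the four base conditions — the single-feature reduction of a
  linear discriminant analysis — with selection at p < 0.05 AND F > 3, both
  strict, and no multiple-testing correction (the filter is a screening
  heuristic, not an inference claim). Zero within-group variance yields
  F = ∞, p = 0 (selected) when group means differ and F = 0 (not selected)
  when all values coincide. p-values come from the F distribution on
  (k−1, N−k) df; permutation p-values were considered and rejected as
  needless at N = 27 with a screening threshold this loose.

## Co-expression networks

Spearman ρ is computed as the Pearson correlation of average-ranked values
(standard tie handling appropriate for count data); the two-sided p-value
uses t = ρ·√((n−2)/(1−ρ²)) on n−2 df, with p = 0 at ρ = ±1. The t
approximation is slightly anticonservative in the extreme tail at n = 12–15;
at the operating point the double threshold (|ρ| > 0.7 AND p < 0.01, both
strict) has an exact null tail of ≈ 0.0092 at n = 13, which the calibration
test checks against the 0.01 bound with a binomial tolerance. Proteins with
constant ranks over a grouping's samples have undefined ρ; their pairs are
excluded and the proteins flagged.

Network nodes default to proteins with ≥ 1 passing edge (isolated nodes
carry no topological information here and would only dilute mean degree);
a flag retains all filtered proteins. Edges carry ρ, p and sign.

## PPI transfer

Evidence filtering keeps an interaction when the database channel exceeds
0.15 **or** the experimental channel exceeds 0.35 (strict, per the
"annotated and/or experimentally determined" convention). Transfer fans the
surviving gene pairs out over all protein pairs mapping to them; every edge
records its source gene pair as an audit trail. Two proteins mapping to the
same gene get no edge: the interaction table cannot contain self-pairs, so
paralog pairs have no supporting row by construction. Duplicate table rows
are merged by per-channel maximum. Condition subnetworks are plain induced
subgraphs on the identified-protein sets, with optional isolated-node
removal and largest-component restriction (the pipeline drops isolated
nodes when reporting, mirroring how interactome node counts are usually
quoted).

## Topology

* **Betweenness**: unnormalized shortest-path betweenness (Brandes), each
  unordered pair counted once, endpoints excluded, per component.
* **Centroid centrality**: C(v) = min over reachable w of γ_v(w) − γ_w(v),
  γ_v(w) = #{u : d(u,v) < d(u,w)} (equidistant nodes count for neither).
  Computed per connected component — inter-component distances are infinite,
  so a global variant would be ill-defined — with isolated nodes at 0. The
  implementation builds the BFS distance matrix per component and
  accumulates γ vectorized; tests compare it against a direct triple-loop
  oracle, exactly.
* **Hub rule**: centrality strictly above the network-wide mean. PPI hubs
  require both betweenness and centroid above mean (AND; OR available as a
  flag — AND is the conservative reading of "values above the average" for
  two centralities, and every AND hub set is a subset of the OR set, which
  the tests assert). Co-expression hubs use degree only.
* **Condition-specific hubs**: for a factor level L, hubs in both networks
  of L and in neither network of the opposite level ("both" rule; an
  "any-network" variant is a flag). The two level sets of a factor are
  disjoint by construction.
* **Differential correlation**: a protein is called with focal grouping g
  iff degree_g > mean degree of network g AND degree_g is the strict maximum
  over the four groupings (absent proteins have degree 0). Ties are never
  called; at most one focal grouping per protein.
* **Edge overlap** between a co-expression network and the PPI network is
  reported pair-level (% of co-expression edges that are also PPI edges,
  the headline) and protein-level (% of co-expression nodes incident to a
  shared edge); undefined on edgeless networks.

## Synthetic data generator

The generator emulates the *count-level* behaviour of a root-mitochondrial
SpC experiment; it does not model peptide/protein inference or peak data.

**Count model.** Counts are negative binomial with common dispersion
(size 12) — SpC data are overdispersed integers — with per-protein log2
baselines and a logistic detection-dropout in −(log2 mean − midpoint),
so low-abundance proteins are missed more often, exactly the regime the 51%
prevalence filter exists for.

**Modules and planted hubs.** Each module is a set of proteins sharing a
latent N(0,1) factor inside its active grouping's samples (log2 loading 1.8,
one higher-loading *anchor* per module at 1.15×), yielding a within-module
correlation ≈ 0.93 and near-complete edge recovery there. Two design choices
deserve explanation because naive alternatives fail:

* *Variance-matched idiosyncratic noise outside the active grouping.* If
  module proteins were flat outside their grouping, the flat samples would
  rank coherently below/above the varying ones and the module would leak
  high Spearman correlations into the two overlapping groupings (measured
  leak: ~38% of pairs above threshold). Members therefore receive
  independent per-protein normal deviates outside the active grouping,
  scaled 1.5× the factor signal; the inflation dilutes the leaked
  correlation (shared variance on the overlapping base condition's samples)
  safely below the edge threshold.
* *Module members, not a single protein, are the planted hubs.* A lone hub
  with k mutually uncorrelated partners is impossible at this threshold:
  squared correlations of one protein to mutually independent partners sum
  to ≤ 1, so partners of a strong hub are themselves correlated at ≈ r² and
  acquire above-mean degrees, destroying any precision target. The planted
  unit of grouping-specific degree is therefore the module: every member's
  degree peaks in the active grouping, and `GroundTruth.planted_hubs` maps
  each grouping to its modules' member sets (anchors recorded separately).

**Differentially expressed proteins** get a +2.5 log2 shift in one base
condition (cycled over conditions) plus 1.0 log2 idiosyncratic noise. The
noise is essential: proteins sharing a shifted condition otherwise form
their own co-expression cliques in the two groupings containing that
condition (their on/off pattern rank-correlates at ≈ 0.75) and surface as
false differential-correlation calls. The default of 8 DE proteins keeps
those residual correlations' degrees below network means while leaving the
F-ratio filter a sensitivity ≥ 0.9 target at these sample sizes (the shift
and noise jointly put the one-way F noncentrality near 16–19).

**Background** proteins are uncorrelated; 95% draw low baselines
(log2 1.5–3.5) and mostly fail the prevalence filter — emulating the bulk of
sporadic low-abundance identifications — and 5% are consistently detected.
This keeps the number of proteins entering each grouping network small
enough that chance correlations (null rate ≈ 0.009 per pair at n = 13) do
not flood the networks; with hundreds of consistently-detected background
proteins the strict-maximum call rule would otherwise fire on null-degree
jitter alone.

**Ortholog map and interaction table.** Each protein maps to one synthetic
reference gene (a configurable fraction of genes receive two proteins);
homology percentages are truncated-normal around 67 (sd 12) on (0, 100].
Interaction sampling favours within-module gene pairs (p_in = 0.9) over
others (p_out = 0.01); scores are drawn so a quarter of rows fall below both
evidence thresholds to exercise the filter.

All randomness flows from a single `numpy` generator seeded by the config;
identical configs are bit-reproducible.

## What passing tests do and do not show

The generator plants clean, block-structured signal with known abundance
tiers; real SpC data have correlated batch structure, abundance-dependent
dispersion, shared-peptide ambiguity and biological co-regulation that is
not block-diagonal. Recovery numbers (hub precision/recall ≈ 0.9/0.98 at
default settings) therefore validate the *implementation* of the rules, not
the expected yield of the rules on real proteomes — on real data the
strict-maximum rule is intentionally liberal and is meant as a screening
step ahead of biological interpretation. Network sizes here (tens of nodes)
are deliberately smaller than published interactome analyses (hundreds of
nodes), scaled to keep the full test suite fast.

## Numerical choices and degenerate inputs

* Strict inequalities everywhere a threshold is quoted ("above the
  average", "> 0.15", "> |0.7|"); boundary cases are pinned in tests.
* Spearman requires ≥ 3 samples (df = n−2 ≥ 1); the t approximation is only
  trusted at the study's n = 12–15, and |ρ| = 1 maps to p = 0 exactly.
* Empty networks yield empty hub sets; empty co-expression networks make
  overlap undefined (reported as not applicable, never 0).
* Mean centrality denominators use all network nodes; with isolated nodes
  dropped at construction, "all nodes" and "connected nodes" coincide.
* Seeds derived inside the acceptance script stay below 2³¹.
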