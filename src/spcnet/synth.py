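"""Synthetic spectral-count proteomics datasets with known planted structure.

The generator emulates a root-mitochondrial spectral-count (SpC) experiment:
a proteins × samples matrix of non-negative integer counts over 27 samples
allocated 6/8/6/7 to the four Fe/Mo base conditions (the unique non-negative
integer solution of the pooled grouping sizes +Fe=12, +Mo=14, −Fe=15, −Mo=13),
plus an ortholog map to a reference species and a STRING-like interaction
table with two evidence-channel scores.

Generative model
----------------
Counts are negative binomial with a common dispersion. The log2 mean of
protein ``p`` in sample ``s`` is::

    log2 mu_ps = b_p + sigma * L_p * z_k(s)   (module proteins)
    log2 mu_ps = b_p + delta * 1[s in c_p]    (differentially expressed)
    log2 mu_ps = b_p                          (background)

where ``b_p`` is a per-protein baseline, ``z_k`` the latent factor of module
``k`` and ``L_p`` the protein's loading on it. Each module is *active* in one
condition grouping: inside the active grouping's samples every member shares
the module factor (planting a grouping-specific co-expression clique); in all
other samples each member receives its own variance-matched idiosyncratic
normal deviate instead. The variance matching matters: if module proteins
were simply flat outside the active grouping, the flat samples would rank
coherently against the varying ones and the module would leak strong rank
correlations into the two overlapping groupings.

Every count is then zeroed with probability logistic in −(log2 mean −
``dropout_midpoint``), emulating stochastic non-identification of
low-abundance proteins. Background baselines are drawn low enough that
dropout makes most background proteins fail a 51% prevalence filter, which
both exercises that filter and keeps chance correlations among the many
background proteins from flooding the grouping networks.

Planted hubs
------------
Each module's members are the proteins whose co-expression degree is
engineered to peak in the module's active grouping, so
``GroundTruth.planted_hubs`` maps each grouping to the member sets of its
modules. One member per module (the *anchor*) gets a higher loading and is
recorded separately in ``GroundTruth.anchors``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import (
    BASE_CONDITIONS,
    GROUPING_ORDER,
    GROUPINGS,
    check_grouping_design,
    samples_for_grouping,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_spc_dataset",
    "generate_ortholog_map",
    "generate_interaction_table",
    "default_config",
]

#: Replicates per base condition solving the pooled grouping sizes
#: (+Fe 12, +Mo 14, −Fe 15, −Mo 13).
DEFAULT_REPS: dict[str, int] = {"+Mo+Fe": 6, "+Mo-Fe": 8, "-Mo+Fe": 6, "-Mo-Fe": 7}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic SpC experiment.

    The defaults are the study conditions every recovery property is stated
    under; see docs/methods.md for the rationale behind each value.
    """

    n_proteins: int = 300
    reps_per_condition: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REPS)
    )
    n_modules: int = 4
    module_size: int = 10
    #: (anchor protein id, active grouping) per module; None derives one
    #: module per grouping in GROUPING_ORDER with the first member as anchor.
    hub_spec: tuple[tuple[str, str], ...] | None = None
    n_de_proteins: int = 8
    de_log2_effect: float = 2.5
    #: sd (log2) of idiosyncratic noise on DE proteins; keeps proteins that
    #: share a shift pattern from forming their own co-expression cliques
    de_noise_sd: float = 1.0
    #: negative-binomial size parameter (larger = less overdispersed)
    nb_dispersion: float = 12.0
    #: baseline log2 mean range for sporadically-identified background
    #: proteins (mostly below the dropout midpoint: these emulate the bulk of
    #: low-abundance identifications that fail the prevalence filter)
    baseline_log_mean_range: tuple[float, float] = (1.5, 3.5)
    #: fraction of background proteins drawn instead from
    #: ``background_high_range`` (consistently identified, uncorrelated)
    background_high_frac: float = 0.05
    background_high_range: tuple[float, float] = (5.0, 7.0)
    #: log2 mean below which detection dropout exceeds 50%
    dropout_midpoint: float = 3.5
    dropout_steepness: float = 1.0
    #: sd (log2 units) of the module factor signal at loading 1
    module_factor_sd: float = 1.8
    anchor_loading: float = 1.15
    #: idiosyncratic noise of module proteins outside the active grouping is
    #: this multiple of the factor signal; >1 dilutes the rank correlation
    #: that the shared base condition would otherwise leak into the two
    #: overlapping groupings
    inactive_noise_inflation: float = 1.5
    #: log2 baseline ranges for module and DE proteins (kept above the
    #: dropout midpoint so planted structure survives the prevalence filter)
    module_log_mean_range: tuple[float, float] = (7.0, 9.0)
    de_log_mean_range: tuple[float, float] = (7.5, 9.0)
    seed: int = 0

    def validate(self) -> None:
        check_grouping_design(self.reps_per_condition)
        if self.n_modules * self.module_size > self.n_proteins:
            raise ValueError("module_size * n_modules exceeds n_proteins")
        if self.n_de_proteins + self.n_modules * self.module_size > self.n_proteins:
            raise ValueError("planted proteins exceed n_proteins")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.hub_spec is not None and len(self.hub_spec) != self.n_modules:
            raise ValueError("hub_spec must name one (protein, grouping) per module")
        if self.hub_spec is not None:
            for _, grouping in self.hub_spec:
                if grouping not in GROUPINGS:
                    raise ValueError(f"unknown grouping {grouping!r} in hub_spec")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated dataset."""

    #: protein -> module index (proteins without a module are absent)
    module_assignment: Mapping[str, int]
    #: module index -> active grouping
    module_grouping: Mapping[int, str]
    #: grouping -> all proteins whose degree is planted to peak there
    planted_hubs: Mapping[str, frozenset[str]]
    #: grouping -> high-loading anchor proteins of its modules
    anchors: Mapping[str, frozenset[str]]
    de_proteins: frozenset[str]
    #: DE protein -> base condition carrying the shift
    de_condition: Mapping[str, str]
    #: within-module protein pairs (sorted tuples); the favoured pairs of
    #: generate_interaction_table
    true_interactions: frozenset[tuple[str, str]]


def default_config(**overrides) -> SimulationConfig:
    """The study-condition configuration, with optional field overrides."""
    return replace(SimulationConfig(), **overrides)


def _protein_ids(n: int) -> list[str]:
    return [f"P{i + 1:04d}" for i in range(n)]


def _sample_layout(reps: Mapping[str, int]) -> tuple[list[str], list[str]]:
    """Sample ids and their base conditions, condition-blocked."""
    samples, conds = [], []
    for cond in BASE_CONDITIONS:
        for r in range(int(reps[cond])):
            samples.append(f"{cond}_r{r + 1}")
            conds.append(cond)
    return samples, conds


def _resolve_modules(
    config: SimulationConfig, proteins: Sequence[str]
) -> tuple[dict[str, int], dict[int, str], dict[int, str]]:
    """Member assignment, active grouping and anchor for each module."""
    m = config.module_size
    assignment = {
        proteins[k * m + j]: k for k in range(config.n_modules) for j in range(m)
    }
    if config.hub_spec is None:
        module_grouping = {
            k: GROUPING_ORDER[k % len(GROUPING_ORDER)] for k in range(config.n_modules)
        }
        anchors = {k: proteins[k * m] for k in range(config.n_modules)}
        return assignment, module_grouping, anchors

    module_grouping, anchors = {}, {}
    for k, (protein, grouping) in enumerate(config.hub_spec):
        module_grouping[k] = grouping
        if protein not in assignment:
            # swap the named protein into module k in place of its default anchor
            if protein not in proteins:
                raise ValueError(f"hub_spec protein {protein!r} not in proteome")
            assignment.pop(proteins[k * m])
            assignment[protein] = k
        elif assignment[protein] != k:
            other = assignment[protein]
            assignment[protein], assignment[proteins[other * m]] = k, other
        anchors[k] = protein
    return assignment, module_grouping, anchors


def generate_spc_dataset(
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series, GroundTruth]:
    """Simulate a spectral-count matrix with planted structure.

    Returns
    -------
    counts : DataFrame (proteins × samples) of non-negative integers
    meta : Series mapping sample id -> base condition
    truth : GroundTruth
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    proteins = _protein_ids(config.n_proteins)
    samples, conds = _sample_layout(config.reps_per_condition)
    n_p, n_s = len(proteins), len(samples)
    meta = pd.Series(conds, index=pd.Index(samples, name="sample"), name="base_condition")

    assignment, module_grouping, anchors = _resolve_modules(config, proteins)
    module_members = {
        k: sorted(p for p, kk in assignment.items() if kk == k)
        for k in range(config.n_modules)
    }
    non_module = [p for p in proteins if p not in assignment]
    de_proteins = non_module[: config.n_de_proteins]
    background = non_module[config.n_de_proteins:]

    idx = {p: i for i, p in enumerate(proteins)}
    log2_mean = np.empty((n_p, n_s))

    lo, hi = config.baseline_log_mean_range
    log2_mean[:] = rng.uniform(lo, hi, size=n_p)[:, None]
    hi_rows = [
        idx[p]
        for p in background
        if rng.random() < config.background_high_frac
    ]
    blo, bhi = config.background_high_range
    if hi_rows:
        log2_mean[hi_rows, :] = rng.uniform(blo, bhi, size=len(hi_rows))[:, None]
    mlo, mhi = config.module_log_mean_range
    for k, members in module_members.items():
        rows = [idx[p] for p in members]
        log2_mean[rows, :] = rng.uniform(mlo, mhi, size=len(rows))[:, None]
    dlo, dhi = config.de_log_mean_range
    de_rows = [idx[p] for p in de_proteins]
    if de_rows:
        log2_mean[de_rows, :] = rng.uniform(dlo, dhi, size=len(de_rows))[:, None]

    # module factors: shared inside the active grouping, variance-matched
    # idiosyncratic noise elsewhere
    cond_arr = np.asarray(conds)
    for k, members in module_members.items():
        active = np.isin(cond_arr, list(GROUPINGS[module_grouping[k]]))
        z = rng.standard_normal(n_s)
        for p in members:
            loading = config.anchor_loading if p == anchors[k] else 1.0
            own = config.inactive_noise_inflation * rng.standard_normal(n_s)
            signal = np.where(active, z, own)
            log2_mean[idx[p], :] += config.module_factor_sd * loading * signal

    # cycle the shifted condition so DE proteins spread over the design
    de_condition = {}
    for i, p in enumerate(de_proteins):
        cond = BASE_CONDITIONS[i % len(BASE_CONDITIONS)]
        de_condition[p] = cond
        log2_mean[idx[p], cond_arr == cond] += config.de_log2_effect
        log2_mean[idx[p], :] += config.de_noise_sd * rng.standard_normal(n_s)

    mu = np.exp2(log2_mean)
    r = config.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    # detection dropout: logistic in −(log2 mean − midpoint)
    p_drop = 1.0 / (
        1.0 + np.exp(config.dropout_steepness * (log2_mean - config.dropout_midpoint))
    )
    counts = np.where(rng.random(size=counts.shape) < p_drop, 0, counts)

    counts_df = pd.DataFrame(
        counts.astype(np.int64),
        index=pd.Index(proteins, name="protein"),
        columns=pd.Index(samples, name="sample"),
    )

    planted: dict[str, set[str]] = {g: set() for g in GROUPING_ORDER}
    anchor_sets: dict[str, set[str]] = {g: set() for g in GROUPING_ORDER}
    for k, members in module_members.items():
        planted[module_grouping[k]].update(members)
        anchor_sets[module_grouping[k]].add(anchors[k])
    true_pairs = frozenset(
        tuple(sorted((a, b)))
        for members in module_members.values()
        for i, a in enumerate(members)
        for b in members[i + 1:]
    )

    truth = GroundTruth(
        module_assignment=dict(assignment),
        module_grouping=dict(module_grouping),
        planted_hubs={g: frozenset(v) for g, v in planted.items()},
        anchors={g: frozenset(v) for g, v in anchor_sets.items()},
        de_proteins=frozenset(de_proteins),
        de_condition=de_condition,
        true_interactions=true_pairs,
    )
    return counts_df, meta, truth


def generate_ortholog_map(
    proteins: Sequence[str],
    mean_homology: float = 67.0,
    seed: int = 0,
    fraction_many_to_one: float = 0.1,
    homology_sd: float = 12.0,
) -> pd.DataFrame:
    """Map each protein to one reference-species gene with a homology %.

    A ``fraction_many_to_one`` of the gene pool receives two proteins
    (recent paralogs mapping to the same ortholog); homology percentages are
    drawn truncated-normal on (0, 100].

    Returns a DataFrame with columns ``protein``, ``gene``, ``homology_pct``.
    """
    if not 0 < mean_homology <= 100:
        raise ValueError("mean_homology must be in (0, 100]")
    rng = np.random.default_rng(seed)
    proteins = list(proteins)
    n = len(proteins)

    n_shared = int(round(fraction_many_to_one * n)) // 2 * 2
    shared = rng.choice(n, size=n_shared, replace=False) if n_shared else np.array([], int)
    gene_of = {}
    gene_counter = 0

    def new_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"AT{(gene_counter - 1) % 5 + 1}G{gene_counter * 10:05d}"

    for a, b in zip(shared[0::2], shared[1::2]):
        g = new_gene()
        gene_of[proteins[a]] = g
        gene_of[proteins[b]] = g
    for p in proteins:
        if p not in gene_of:
            gene_of[p] = new_gene()

    a = (0.0 - mean_homology) / homology_sd
    b = (100.0 - mean_homology) / homology_sd
    hom = stats.truncnorm.rvs(
        a, b, loc=mean_homology, scale=homology_sd, size=n, random_state=rng
    )
    return pd.DataFrame(
        {"protein": proteins, "gene": [gene_of[p] for p in proteins], "homology_pct": hom}
    )


def generate_interaction_table(
    truth: GroundTruth,
    p_in: float = 0.9,
    p_out: float = 0.01,
    seed: int = 0,
    ortholog_map: pd.DataFrame | None = None,
    frac_subthreshold: float = 0.25,
    db_threshold: float = 0.15,
    exp_threshold: float = 0.35,
) -> pd.DataFrame:
    """Sample a STRING-like interaction table from planted module structure.

    Gene pairs whose genes share a planted module interact with probability
    ``p_in``, all other pairs with ``p_out``. Each sampled interaction gets a
    ``database_score`` and an ``experimental_score``; a ``frac_subthreshold``
    fraction is drawn below both score thresholds so evidence filtering has
    something to remove.

    When ``ortholog_map`` is given, pairs are drawn over its genes (a gene
    inherits the module of any protein mapping to it); otherwise protein ids
    double as gene ids.
    """
    if p_in < p_out:
        raise ValueError("p_in must be >= p_out")
    rng = np.random.default_rng(seed)

    if ortholog_map is None:
        module_of = dict(truth.module_assignment)
        genes = sorted(
            set(module_of) | {p for pair in truth.true_interactions for p in pair}
        )
        if not genes:  # no planted structure at all
            genes = []
    else:
        module_of = {}
        for protein, gene in zip(ortholog_map["protein"], ortholog_map["gene"]):
            if protein in truth.module_assignment:
                module_of[gene] = truth.module_assignment[protein]
        genes = sorted(ortholog_map["gene"].unique())

    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            same = ga in module_of and gb in module_of and module_of[ga] == module_of[gb]
            if rng.random() >= (p_in if same else p_out):
                continue
            if rng.random() < frac_subthreshold:
                db = rng.uniform(0.0, db_threshold)
                exp = rng.uniform(0.0, exp_threshold)
            else:
                u = rng.random()
                if u < 0.4:  # database evidence only
                    db = rng.uniform(db_threshold + 1e-6, 1.0)
                    exp = rng.uniform(0.0, exp_threshold)
                elif u < 0.8:  # experimental evidence only
                    db = rng.uniform(0.0, db_threshold)
                    exp = rng.uniform(exp_threshold + 1e-6, 1.0)
                else:  # both channels
                    db = rng.uniform(db_threshold + 1e-6, 1.0)
                    exp = rng.uniform(exp_threshold + 1e-6, 1.0)
            a, b = sorted((ga, gb))
            rows.append((a, b, db, exp))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "database_score", "experimental_score"]
    )
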