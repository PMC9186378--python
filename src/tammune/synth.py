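"""Synthetic cohort generators with planted ground truth.

Three generators emulate the statistical structure of the study inputs so
the whole pipeline is testable without external accessions:

* :func:`gen_sc_cohort` — single cells along a monocyte-to-macrophage
  differentiation axis (three archetype subclusters), with early/late
  marker genes, ``MT-`` mitochondrial genes, per-cell quality variation
  spanning the QC thresholds, and contiguous planted copy-number segments.
* :func:`gen_bulk_cohort` — bulk tumors as immune-cell-fraction mixtures
  over a reference basis, with a planted chemokine-driven hot/cold
  phenotype, exponential survival times, and logistic-model response labels.
* :func:`gen_ppi` — a sparse background interaction graph with a planted
  dense hub module.

Every generator is deterministic under its config seed and returns its
ground truth alongside the data, because downstream acceptance tests are
recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "ConfigError",
    "ScSimConfig",
    "BulkSimConfig",
    "GraphSimConfig",
    "ScCohort",
    "BulkCohort",
    "gen_sc_cohort",
    "gen_bulk_cohort",
    "gen_ppi",
    "CHEMOKINES",
    "LM22_TYPES",
    "KEY_CELL_TYPES",
]


class ConfigError(ValueError):
    """A simulation config violates one of its invariants."""


#: The four-chemokine axis that defines the immune hot/cold phenotype.
CHEMOKINES = ("CXCL9", "CXCL10", "CXCL11", "CCL5")

#: LM22-style immune cell type vocabulary (22 leukocyte types).
LM22_TYPES = (
    "B.cells.naive", "B.cells.memory", "Plasma.cells",
    "T.cells.CD8", "T.cells.CD4.naive", "T.cells.CD4.memory.resting",
    "T.cells.CD4.memory.activated", "T.cells.follicular.helper",
    "T.cells.regulatory.Tregs", "T.cells.gamma.delta",
    "NK.cells.resting", "NK.cells.activated",
    "Monocytes", "Macrophages.M0", "Macrophages.M1", "Macrophages.M2",
    "Dendritic.cells.resting", "Dendritic.cells.activated",
    "Mast.cells.resting", "Mast.cells.activated",
    "Eosinophils", "Neutrophils",
)

#: Non-immune compartment column appended to the simulated basis.
MALIGNANT = "Malignant.cells"

#: The three fraction features used (with the chemokine grades) by the
#: response predictor.
KEY_CELL_TYPES = ("Macrophages.M1", "T.cells.CD8", "T.cells.CD4.memory.activated")


# ======================================================================
# single-cell cohort
# ======================================================================

@dataclass
class ScSimConfig:
    """Single-cell differentiation cohort parameters.

    Latent time is uniform on [0, 1]; early markers decay with it, late
    markers rise. Counts come from a negative-binomial model (log-mean
    structure plus overdispersion) so detected-gene counts and
    mitochondrial fractions behave like real QC statistics.
    ``cnv_segments`` are (start_gene_index, end_gene_index_exclusive,
    multiplicative_shift) triples applied to a subset of cells.
    """

    n_cells: int = 500
    n_genes: int = 1000
    n_mito_genes: int = 10
    n_early_markers: int = 40
    n_late_markers: int = 40
    early_effect_log2fc: float = 2.0
    late_effect_log2fc: float = 2.0
    noise_sd: float = 0.3
    cnv_segments: list[tuple[int, int, float]] = field(default_factory=list)
    cnv_cell_fraction: float = 0.5
    dispersion: float = 10.0
    base_log2_mean: float = 3.0
    base_log2_sd: float = 0.8
    low_quality_fraction: float = 0.02
    high_mito_fraction: float = 0.02
    genes_per_chromosome: int = 250
    seed: int = 0

    def validate(self) -> None:
        if self.n_early_markers + self.n_late_markers + self.n_mito_genes > self.n_genes:
            raise ConfigError(
                "n_early_markers + n_late_markers + n_mito_genes exceeds n_genes"
            )
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.early_effect_log2fc <= 0 or self.late_effect_log2fc <= 0:
            raise ConfigError("marker effect log2FC must be positive")
        if not 0 <= self.cnv_cell_fraction <= 1:
            raise ConfigError("cnv_cell_fraction must be in [0, 1]")
        for seg in self.cnv_segments:
            start, end, shift = seg
            if not (0 <= start < end <= self.n_genes):
                raise ConfigError(f"cnv segment {seg} outside gene index range")
            if shift <= 0:
                raise ConfigError(f"cnv segment {seg} needs a positive multiplicative shift")
        if self.n_cells < 2 or self.dispersion <= 0:
            raise ConfigError("need n_cells >= 2 and dispersion > 0")


@dataclass
class ScCohort:
    """A simulated single-cell cohort plus its planted truth."""

    counts: ExpressionMatrix
    latent_time: pd.Series
    subcluster: pd.Series          # C1 (early) / C2 (transitional) / C0 (mature)
    early_genes: list[str]
    late_genes: list[str]
    mito_genes: list[str]
    cnv_profile: pd.Series         # per-gene planted log2 shift (step function)
    cnv_cells: list[str]
    gene_order: pd.DataFrame       # BED-like chrom/start/end/gene in matrix order


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    # var = m + m^2/theta; numpy parameterizes by (n, p)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, np.clip(p, 1e-12, 1.0))


def gen_sc_cohort(cfg: ScSimConfig) -> ScCohort:
    """Simulate raw single-cell counts along a differentiation axis."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    n_g, n_c = cfg.n_genes, cfg.n_cells
    mito_idx = np.arange(n_g - cfg.n_mito_genes, n_g)
    rest = rng.permutation(n_g - cfg.n_mito_genes)
    early_idx = np.sort(rest[: cfg.n_early_markers])
    late_idx = np.sort(rest[cfg.n_early_markers : cfg.n_early_markers + cfg.n_late_markers])

    gene_ids = np.array([f"G{i:04d}" for i in range(n_g)], dtype=object)
    gene_ids[mito_idx] = [f"MT-{j}" for j in range(len(mito_idx))]
    cell_ids = [f"cell{i:04d}" for i in range(n_c)]

    t = rng.uniform(0.0, 1.0, size=n_c)
    subcluster = np.where(t < 1 / 3, "C1", np.where(t < 2 / 3, "C2", "C0"))

    base = rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n_g)
    # markers are well-expressed genes: solid baseline keeps the planted
    # log2 fold change from being crushed by the +1 pseudocount downstream
    base[early_idx] = rng.normal(cfg.base_log2_mean + 1.5, 0.4, size=early_idx.size)
    base[late_idx] = rng.normal(cfg.base_log2_mean + 1.5, 0.4, size=late_idx.size)
    log2_mu = np.tile(base[:, None], (1, n_c))
    # early markers decay along latent time, late markers rise; the
    # logistic profile keeps the early-vs-late archetype contrast at the
    # configured log2FC while staying monotone along the axis
    gate_early = 1.0 / (1.0 + np.exp(-12.0 * (0.5 - t)))
    gate_late = 1.0 - gate_early
    log2_mu[early_idx] += cfg.early_effect_log2fc * gate_early[None, :]
    log2_mu[late_idx] += cfg.late_effect_log2fc * gate_late[None, :]
    # mitochondrial genes get a solid baseline so mito% is measurable
    log2_mu[mito_idx] += 1.0

    # planted copy-number segments on a subset of cells
    n_cnv = int(round(cfg.cnv_cell_fraction * n_c))
    cnv_cell_idx = rng.choice(n_c, size=n_cnv, replace=False) if n_cnv else np.array([], int)
    cnv_profile = np.zeros(n_g)
    for start, end, shift in cfg.cnv_segments:
        cnv_profile[start:end] += np.log2(shift)
    if n_cnv:
        log2_mu[:, cnv_cell_idx] += cnv_profile[:, None]

    # per-cell technical variation: library size, dropouts, mito load
    size = rng.normal(0.0, 0.3, size=n_c)
    n_low = int(round(cfg.low_quality_fraction * n_c))
    n_himito = int(round(cfg.high_mito_fraction * n_c))
    special = rng.choice(n_c, size=n_low + n_himito, replace=False)
    low_idx, himito_idx = special[:n_low], special[n_low:]
    size[low_idx] -= 6.0                       # near-empty droplets: few detected genes
    log2_mu[np.ix_(mito_idx, himito_idx)] += 5.0  # dying cells: mito-dominated

    log2_mu += size[None, :]
    if cfg.noise_sd > 0:
        log2_mu += rng.normal(0.0, cfg.noise_sd, size=log2_mu.shape)

    counts = _nb_sample(rng, np.exp2(log2_mu), cfg.dispersion).astype(float)

    n_chrom = max(1, int(np.ceil(n_g / cfg.genes_per_chromosome)))
    chrom = [f"chr{i // cfg.genes_per_chromosome + 1}" for i in range(n_g)]
    start_pos = [(i % cfg.genes_per_chromosome) * 1000 for i in range(n_g)]
    gene_order = pd.DataFrame(
        {"chrom": chrom, "start": start_pos,
         "end": [s + 500 for s in start_pos], "gene": gene_ids}
    )
    del n_chrom

    return ScCohort(
        counts=ExpressionMatrix(pd.DataFrame(counts, index=gene_ids, columns=cell_ids)),
        latent_time=pd.Series(t, index=cell_ids, name="latent_time"),
        subcluster=pd.Series(subcluster, index=cell_ids, name="subcluster"),
        early_genes=list(gene_ids[early_idx]),
        late_genes=list(gene_ids[late_idx]),
        mito_genes=list(gene_ids[mito_idx]),
        cnv_profile=pd.Series(cnv_profile, index=gene_ids, name="log2_shift"),
        cnv_cells=[cell_ids[i] for i in sorted(cnv_cell_idx)],
        gene_order=gene_order,
    )


# ======================================================================
# bulk cohort
# ======================================================================

@dataclass
class BulkSimConfig:
    """Bulk mixture cohort parameters.

    Expression is ``basis @ fractions`` per sample (linear scale) with a
    multiplicative ``2**hot_effect_log2fc`` chemokine boost in hot samples
    and additive Gaussian noise. The basis holds the 22 LM22-style immune
    profiles plus a malignant compartment, so the summed immune fraction
    (1 - malignant) varies across tumors. Survival is exponential with a
    hot-vs-cold hazard ratio; response labels follow a logistic model on
    the 7 predictor features (4 chemokine levels + 3 key cell fractions).
    """

    n_samples: int = 200
    n_genes: int = 500
    n_cell_types: int = 22
    basis_matrix: pd.DataFrame | None = None
    hot_fraction: float = 0.5
    chemokine_gene_ids: tuple[str, str, str, str] = CHEMOKINES
    hot_effect_log2fc: float = 2.0
    survival_hazard_ratio_hot_vs_cold: float = 0.5
    response_model_coefficients: tuple[float, ...] = (1.5, 1.5, 1.5, 1.5, 1.0, 1.0, 1.0)
    response_intercept: float = 0.0
    noise_sd: float = 0.0
    include_malignant: bool = True
    plant_a_subtypes: int = 0      # 0, or 3 to plant the A1/A2/A3 + B structure
    n_early_genes: int = 30
    baseline_hazard: float = 0.02
    censoring_hazard: float = 0.006
    marker_strength: float = 16.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.hot_fraction < 1:
            raise ConfigError("hot_fraction must lie in (0, 1)")
        if self.survival_hazard_ratio_hot_vs_cold <= 0:
            raise ConfigError("survival hazard ratio must be positive")
        if len(self.response_model_coefficients) != 7:
            raise ConfigError("response model needs exactly 7 coefficients")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if len(set(self.chemokine_gene_ids)) != 4:
            raise ConfigError("need 4 distinct chemokine gene ids")
        if self.plant_a_subtypes not in (0, 3):
            raise ConfigError("plant_a_subtypes must be 0 or 3")
        if self.n_samples < 8:
            raise ConfigError("need at least 8 samples")


@dataclass
class BulkCohort:
    """A simulated bulk cohort plus its planted truth."""

    expression: ExpressionMatrix   # linear scale, genes x samples
    basis: pd.DataFrame            # genes x cell types (incl. malignant column)
    true_fractions: pd.DataFrame   # samples x cell types, rows on the simplex
    hot_labels: pd.Series          # 'hot' / 'cold'
    survival: pd.DataFrame         # columns time, event
    response: pd.Series            # 0/1 (1 = responder, CR/PR)
    subtypes: pd.Series | None     # A1/A2/A3/B when planted, else None
    early_genes: list[str]


def _make_basis(rng: np.random.Generator, gene_ids: list[str], types: list[str],
                chemokines: tuple[str, ...], strength: float) -> pd.DataFrame:
    """Reference profiles: lognormal baseline + exclusive marker blocks per type."""
    n_g, n_t = len(gene_ids), len(types)
    basis = rng.lognormal(mean=1.0, sigma=0.5, size=(n_g, n_t))
    non_chemo = [i for i, g in enumerate(gene_ids) if g not in chemokines]
    markers = rng.permutation(non_chemo)
    block = max(2, len(non_chemo) // n_t)
    for j in range(n_t):
        idx = markers[j * block : (j + 1) * block]
        basis[idx, j] *= strength
    # chemokines sit in the macrophage/T compartments of the basis
    chemo_rows = [gene_ids.index(g) for g in chemokines]
    for j, name in enumerate(types):
        if name in KEY_CELL_TYPES:
            basis[chemo_rows, j] *= 2.0
    return pd.DataFrame(basis, index=gene_ids, columns=types)


def gen_bulk_cohort(cfg: BulkSimConfig) -> BulkCohort:
    """Simulate a bulk tumor cohort as basis x fractions mixtures."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    types = list(LM22_TYPES[: cfg.n_cell_types])
    if len(types) < cfg.n_cell_types:
        types += [f"Cell.type.{i}" for i in range(len(types), cfg.n_cell_types)]
    if cfg.include_malignant:
        types = types + [MALIGNANT]

    if cfg.basis_matrix is not None:
        basis = cfg.basis_matrix.copy()
        gene_ids = list(basis.index)
        types = list(basis.columns)
    else:
        gene_ids = list(cfg.chemokine_gene_ids) + [
            f"G{i:04d}" for i in range(cfg.n_genes - 4)
        ]
        basis = _make_basis(rng, gene_ids, types, cfg.chemokine_gene_ids,
                            cfg.marker_strength)
    B = basis.to_numpy(dtype=float)
    if np.linalg.matrix_rank(B) < B.shape[1]:
        raise ConfigError("basis matrix columns are linearly dependent")

    n = cfg.n_samples
    sample_ids = [f"S{i:03d}" for i in range(n)]
    n_hot = int(round(cfg.hot_fraction * n))
    hot = np.zeros(n, dtype=bool)
    hot[rng.choice(n, size=n_hot, replace=False)] = True

    # ---- fractions: immune Dirichlet + malignant compartment ----------
    alpha = np.ones(cfg.n_cell_types)
    frac = np.empty((n, len(types)))
    key_idx = [types.index(t) for t in KEY_CELL_TYPES if t in types]
    subtypes = np.empty(n, dtype=object) if cfg.plant_a_subtypes else None
    if cfg.plant_a_subtypes:
        hot_ids = np.flatnonzero(hot)
        groups = np.array_split(rng.permutation(hot_ids), 3)
    for i in range(n):
        a = alpha.copy()
        if hot[i]:
            for k in key_idx:
                a[k] = 6.0            # infiltration by the key effector types
        imm = rng.dirichlet(a)
        if cfg.include_malignant:
            if cfg.plant_a_subtypes and hot[i]:
                g = next(j for j, grp in enumerate(groups) if i in grp)
                subtypes[i] = f"A{g + 1}"
                # infiltration gradient A1 > A2 > A3, all clearly above B
                mal = rng.beta(2, 8) * 0.2 + (0.10, 0.25, 0.40)[g]
            elif hot[i]:
                mal = rng.beta(2, 5)
            else:
                if cfg.plant_a_subtypes:
                    subtypes[i] = "B"
                    mal = 0.58 + rng.beta(5, 5) * 0.25
                else:
                    mal = rng.beta(8, 3)
            frac[i] = np.concatenate([imm * (1 - mal), [mal]])
        else:
            frac[i] = imm
            if cfg.plant_a_subtypes:
                subtypes[i] = f"A{rng.integers(1, 4)}" if hot[i] else "B"
    frac /= frac.sum(axis=1, keepdims=True)

    # ---- expression = basis @ fractions (+ hot chemokine boost) -------
    expr = B @ frac.T
    chemo_rows = [gene_ids.index(g) for g in cfg.chemokine_gene_ids]
    expr[np.ix_(chemo_rows, np.flatnonzero(hot))] *= 2.0 ** cfg.hot_effect_log2fc

    # early-differentiation signature genes appended for the step-2 classifier
    early_genes: list[str] = []
    if cfg.plant_a_subtypes:
        early_genes = [f"EG{i:03d}" for i in range(cfg.n_early_genes)]
        eg = rng.lognormal(1.0, 0.3, size=(cfg.n_early_genes, n))
        blocks = np.array_split(np.arange(cfg.n_early_genes), 3)
        for g_idx, grp in enumerate(groups):
            eg[np.ix_(blocks[g_idx], grp)] *= 2.0 ** 2.5
        expr = np.vstack([expr, eg])
        gene_ids = gene_ids + early_genes

    if cfg.noise_sd > 0:
        expr = expr + rng.normal(0.0, cfg.noise_sd, size=expr.shape)
        expr = np.clip(expr, 0.0, None)

    # ---- survival ------------------------------------------------------
    hazard = cfg.baseline_hazard * np.where(
        hot, cfg.survival_hazard_ratio_hot_vs_cold, 1.0
    )
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / cfg.censoring_hazard, size=n)
    event = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)

    # ---- response: logistic model on the 7 predictor features ---------
    log_chemo = np.log2(expr[chemo_rows] + 1.0)          # 4 x n
    feats = np.vstack([log_chemo, frac[:, key_idx].T])   # 7 x n
    z = (feats - feats.mean(axis=1, keepdims=True)) / feats.std(axis=1, keepdims=True)
    eta = cfg.response_intercept + np.asarray(cfg.response_model_coefficients) @ z
    p_resp = 1.0 / (1.0 + np.exp(-eta))
    response = (rng.uniform(size=n) < p_resp).astype(int)

    return BulkCohort(
        expression=ExpressionMatrix(pd.DataFrame(expr, index=gene_ids, columns=sample_ids)),
        basis=basis,
        true_fractions=pd.DataFrame(frac, index=sample_ids, columns=types),
        hot_labels=pd.Series(np.where(hot, "hot", "cold"), index=sample_ids, name="phenotype"),
        survival=pd.DataFrame({"time": time, "event": event}, index=sample_ids),
        response=pd.Series(response, index=sample_ids, name="response"),
        subtypes=pd.Series(subtypes, index=sample_ids, name="subtype")
        if subtypes is not None else None,
        early_genes=early_genes,
    )


# ======================================================================
# interaction graph
# ======================================================================

@dataclass
class GraphSimConfig:
    """Background G(n, p) graph plus a planted dense module."""

    n_background_nodes: int = 200
    background_edge_probability: float = 0.02
    planted_module_size: int = 12
    planted_module_density: float = 1.0
    #: module-to-background edge probability; hub modules are not only
    #: internally dense but also wired into the rest of the network
    #: (None = 4x the background probability)
    module_external_edge_probability: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.background_edge_probability < 1:
            raise ConfigError("background_edge_probability must lie in (0, 1)")
        if not 0 < self.planted_module_density <= 1:
            raise ConfigError("planted_module_density must lie in (0, 1]")
        if self.planted_module_density <= self.background_edge_probability:
            raise ConfigError(
                "planted module density must exceed background edge probability"
            )
        if self.planted_module_size < 2 or self.planted_module_size > self.n_background_nodes:
            raise ConfigError("planted module size must be in [2, n_background_nodes]")


def gen_ppi(cfg: GraphSimConfig) -> tuple[nx.Graph, list[str]]:
    """Simulate an interaction network with a planted dense hub module."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_background_nodes
    names = [f"P{i:04d}" for i in range(n)]

    g = nx.Graph()
    g.add_nodes_from(names)
    iu, ju = np.triu_indices(n, k=1)
    keep = rng.uniform(size=iu.size) < cfg.background_edge_probability
    g.add_edges_from((names[a], names[b]) for a, b in zip(iu[keep], ju[keep]))

    module = sorted(rng.choice(n, size=cfg.planted_module_size, replace=False))
    for ai, a in enumerate(module):
        for b in module[ai + 1 :]:
            if cfg.planted_module_density >= 1.0 or rng.uniform() < cfg.planted_module_density:
                g.add_edge(names[a], names[b])
    p_ext = cfg.module_external_edge_probability
    if p_ext is None:
        p_ext = min(1.0, 4.0 * cfg.background_edge_probability)
    module_set = set(module)
    outside = [i for i in range(n) if i not in module_set]
    for a in module:
        extra = rng.uniform(size=len(outside)) < p_ext
        g.add_edges_from((names[a], names[b]) for b in np.array(outside)[extra])
    return g, [names[i] for i in module]
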