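"""Single-cell QC and differentiation-signature derivation.

QC removes unreliable genes and cells with the standard droplet thresholds:
genes detected in fewer than 3 cells; cells with more than 4,500 or fewer
than 200 detected genes; cells whose mitochondrial (``MT-``) transcripts
exceed 10% of counts. Differential expression between the early (monocyte)
and late (mature macrophage) archetypes uses a per-gene two-sided Wilcoxon
rank-sum test on log2(x+1) expression with Benjamini-Hochberg FDR control;
genes beyond |log2FC| > 1.3 at FDR < 0.05 form the early/late
differentiation signatures. All threshold comparisons are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "SignaturePair",
    "qc_filter",
    "normalize_counts",
    "wilcoxon_de",
    "split_signatures",
    "cohort_degs",
]


@dataclass(frozen=True)
class QcThresholds:
    """Droplet QC cutoffs; all comparisons are strict inequalities."""

    min_cells_per_gene: int = 3
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 4500
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.min_genes_per_cell >= self.max_genes_per_cell:
            raise ValueError("min_genes_per_cell must be < max_genes_per_cell")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class QcReport:
    n_genes_removed: int
    n_cells_removed: int
    n_genes_kept: int
    n_cells_kept: int


@dataclass(frozen=True)
class SignaturePair:
    """Disjoint early/late differentiation gene signatures."""

    early_genes: frozenset[str]
    late_genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.early_genes & self.late_genes:
            raise ValueError("early and late signatures must be disjoint")


def qc_filter(
    raw: ExpressionMatrix,
    thr: QcThresholds = QcThresholds(),
    mito_prefix: str = "MT-",
) -> tuple[ExpressionMatrix, QcReport]:
    """Filter low-support genes, then out-of-range and mito-heavy cells.

    Gene filtering (detected in fewer than ``min_cells_per_gene`` cells)
    runs first; cell thresholds are then evaluated on the surviving genes.
    Order matters and survivor ordering is preserved. Raises if the input
    is log-scale or if nothing survives.
    """
    if raw.is_log:
        raise ValueError("qc_filter requires count-scale (non-log) input")
    counts = raw.values
    detected = counts > 0

    gene_keep = detected.sum(axis=1) >= thr.min_cells_per_gene
    if not gene_keep.any():
        raise ValueError("all genes or all cells removed by QC filtering")
    counts = counts[gene_keep]
    detected = detected[gene_keep]
    gene_ids = np.asarray(raw.gene_ids, dtype=object)[gene_keep]

    genes_per_cell = detected.sum(axis=0)
    is_mito = np.array([g.startswith(mito_prefix) for g in gene_ids])
    total = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, counts[is_mito].sum(axis=0) / np.maximum(total, 1), 0.0)

    cell_keep = (
        (genes_per_cell >= thr.min_genes_per_cell)
        & (genes_per_cell <= thr.max_genes_per_cell)
        & (mito_frac <= thr.max_mito_fraction)
    )
    if not gene_keep.any() or not cell_keep.any():
        raise ValueError("all genes or all cells removed by QC filtering")

    out = raw.data.loc[gene_keep, :].loc[:, cell_keep]
    report = QcReport(
        n_genes_removed=int((~gene_keep).sum()),
        n_cells_removed=int((~cell_keep).sum()),
        n_genes_kept=int(gene_keep.sum()),
        n_cells_kept=int(cell_keep.sum()),
    )
    return ExpressionMatrix(out.copy(), is_log=False, meta=dict(raw.meta)), report


def normalize_counts(
    raw: ExpressionMatrix, target_sum: float = 1e4
) -> ExpressionMatrix:
    """Library-size normalization: scale each cell to ``target_sum`` counts.

    Removes per-cell capture-depth variation before distance-based steps
    (embedding, clustering). Input must be count scale; cells with zero
    total are rejected.
    """
    if raw.is_log:
        raise ValueError("normalize_counts requires count-scale input")
    totals = raw.data.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0][:5])
        raise ValueError(f"cells with zero total counts: {bad}")
    return ExpressionMatrix(
        raw.data * (target_sum / totals), is_log=False, meta=dict(raw.meta)
    )


def wilcoxon_de(
    expr: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum DE of group A vs group B.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (mean log2
    expression in A minus B), ``p`` (normal approximation with continuity
    and tie correction) and ``fdr`` (Benjamini-Hochberg). Expression is
    log2(x+1)-transformed if not already on log scale.
    """
    a, b = list(group_a), list(group_b)
    overlap = set(a) & set(b)
    if overlap:
        raise ValueError(f"groups overlap: {sorted(overlap)[:5]}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 samples")
    unknown = (set(a) | set(b)) - set(expr.sample_ids)
    if unknown:
        raise ValueError(f"unknown sample ids: {sorted(unknown)[:5]}")

    log = expr.to_log2()
    xa = log.data[a].to_numpy(dtype=float)
    xb = log.data[b].to_numpy(dtype=float)

    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    # vectorized over genes: asymptotic Mann-Whitney with ties + continuity
    res = stats.mannwhitneyu(
        xa, xb, axis=1, alternative="two-sided", method="asymptotic"
    )
    p = np.asarray(res.pvalue, dtype=float)
    # genes constant across both groups: no evidence either way
    constant = (xa.std(axis=1) == 0) & (xb.std(axis=1) == 0) & (
        xa[:, 0] == xb[:, 0]
    )
    p[constant] = 1.0
    fdr = benjamini_hochberg(p)
    return pd.DataFrame({"log2fc": log2fc, "p": p, "fdr": fdr}, index=log.gene_ids)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def split_signatures(
    de: pd.DataFrame, lfc_cut: float = 1.3, fdr_cut: float = 0.05
) -> SignaturePair:
    """Threshold a DE table into early (up) / late (down) signatures.

    Early: log2FC > ``lfc_cut`` and FDR < ``fdr_cut``; late: log2FC <
    -``lfc_cut`` and FDR < ``fdr_cut``. Strict inequalities throughout.
    """
    sig = de["fdr"] < fdr_cut
    early = frozenset(de.index[(de["log2fc"] > lfc_cut) & sig])
    late = frozenset(de.index[(de["log2fc"] < -lfc_cut) & sig])
    return SignaturePair(early_genes=early, late_genes=late)


def cohort_degs(
    de: pd.DataFrame,
    lfc_cut: float,
    fdr_cut: float = 0.05,
    direction: str = "up",
) -> set[str]:
    """Thresholded DEG set for one cohort, in one direction.

    Cohort-appropriate cuts differ by platform (|log2FC| > 1 for RNA-seq,
    > 0.2 for arrays, both at FDR < 0.05); cross-cohort overlap is a plain
    set intersection of the returned sets.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if de.empty:
        return set()
    sig = de["fdr"] < fdr_cut
    if direction == "up":
        mask = (de["log2fc"] > lfc_cut) & sig
    else:
        mask = (de["log2fc"] < -lfc_cut) & sig
    return set(de.index[mask])
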