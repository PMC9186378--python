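"""Immune-cell fraction estimation from bulk expression.

Bulk tumors are modelled as linear mixtures of reference cell-type
profiles (an LM22-style basis). Per sample, fractions solve a
non-negative least-squares problem on the shared, per-gene standardized
genes, then renormalize to the simplex — the deterministic counterpart of
signature-matrix deconvolution. Immune/stromal scores are ssGSEA of
user-supplied gene sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .matrix import ExpressionMatrix
from . import score as _score

__all__ = ["deconvolve", "immune_stromal_score"]


def deconvolve(bulk: ExpressionMatrix, basis: pd.DataFrame) -> pd.DataFrame:
    """Estimate cell-type fractions per bulk sample by NNLS on the basis.

    Genes are restricted to the shared set; the non-negative weights are
    renormalized to the simplex, which also makes the result invariant
    to positive rescaling of a sample.

    Parameters
    ----------
    bulk:
        Linear-scale bulk expression (genes x samples).
    basis:
        Reference profiles, genes x cell types, non-negative, linearly
        independent columns.

    Returns
    -------
    DataFrame of samples x cell types; each row is non-negative and sums
    to 1 (relative fractions).
    """
    if bulk.is_log:
        raise ValueError("deconvolve requires linear-scale bulk expression")
    B = basis.to_numpy(dtype=float)
    if (B < 0).any():
        raise ValueError("basis profiles must be non-negative")
    if (B.sum(axis=1) == 0).any():
        raise ValueError("basis contains all-zero gene rows")

    shared = [g for g in basis.index if g in set(bulk.gene_ids)]
    n_types = basis.shape[1]
    if len(shared) < n_types:
        raise ValueError(
            f"only {len(shared)} shared genes for {n_types} cell types; "
            "need at least as many genes as types"
        )

    A = basis.loc[shared].to_numpy(dtype=float)
    Y = bulk.data.loc[shared].to_numpy(dtype=float)

    zero = np.flatnonzero(Y.sum(axis=0) == 0)
    if zero.size:
        raise ValueError(f"all-zero bulk sample(s): {[bulk.sample_ids[i] for i in zero]}")

    # unweighted NNLS: under additive measurement noise the plain
    # least-squares fit is the best linear unbiased estimator, whereas
    # per-gene standardization up-weights low-signal genes and degrades
    # recovery (and row-centering destroys identifiability outright)
    out = np.empty((Y.shape[1], n_types))
    for j in range(Y.shape[1]):
        f, _ = nnls(A, Y[:, j])
        if f.sum() == 0:
            raise ValueError(f"sample {bulk.sample_ids[j]!r} yields an all-zero fit")
        out[j] = f / f.sum()
    return pd.DataFrame(out, index=bulk.sample_ids, columns=list(basis.columns))


def immune_stromal_score(
    expr: ExpressionMatrix,
    immune_set: list[str],
    stromal_set: list[str],
) -> pd.DataFrame:
    """Per-sample immune and stromal scores via ssGSEA of the two sets."""
    sets = {"immune_score": list(immune_set), "stromal_score": list(stromal_set)}
    for name, genes in sets.items():
        if not set(genes) & set(expr.gene_ids):
            raise ValueError(f"gene set {name!r} has no overlap with expression genes")
    return _score.ssgsea(expr, sets)
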