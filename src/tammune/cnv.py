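"""Windowed relative copy-number estimation from expression.

A cell's relative copy number at gene position ``i`` is the mean of its
reference-centred log2 expression over the 101-gene window ``[i-50,
i+50]`` along the genomic gene order: CNV_k(i) = sum_{j=i-50}^{i+50}
E_k(O_j) / 101, where E is log2(expr+1) minus the per-gene mean over
reference cells (clipped for outlier robustness). Windows truncate at
chromosome ends (dividing by the actual member count) and never span
chromosomes. Gain/loss calls threshold the profile symmetrically at
+-0.2 log2 units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = ["infer_cnv_profile", "call_gain_loss"]


def _windowed_mean(x: np.ndarray, half_window: int) -> np.ndarray:
    """Truncated moving average along axis 1 (cells x genes)."""
    n = x.shape[1]
    cs = np.cumsum(x, axis=1)
    cs = np.concatenate([np.zeros((x.shape[0], 1)), cs], axis=1)
    idx = np.arange(n)
    lo = np.maximum(idx - half_window, 0)
    hi = np.minimum(idx + half_window, n - 1)
    return (cs[:, hi + 1] - cs[:, lo]) / (hi - lo + 1)


def infer_cnv_profile(
    expr: ExpressionMatrix,
    reference_cells: list[str],
    order: pd.DataFrame,
    half_window: int = 50,
    clip: float = 3.0,
) -> pd.DataFrame:
    """Per-cell windowed relative copy-number profile along the gene order.

    Parameters
    ----------
    expr:
        Count-scale (or log) expression, genes x cells.
    reference_cells:
        Cells defining the diploid baseline (e.g. normal blood cells);
        must be a non-empty subset of the matrix cells.
    order:
        BED-like frame with columns chrom/start/end/gene giving the
        genomic gene order; every listed gene must be in the matrix.
    half_window:
        Genes on each side of the focal gene (window size 2*half_window+1).
    clip:
        Symmetric bound applied to centred log2 expression before
        windowing; None or 0 disables clipping.

    Returns
    -------
    DataFrame cells x ordered genes of relative copy-number scores
    (log2-ratio units).
    """
    refs = list(reference_cells)
    if not refs:
        raise ValueError("reference_cells must be non-empty")
    missing_ref = [c for c in refs if c not in set(expr.sample_ids)]
    if missing_ref:
        raise ValueError(f"reference cells not in matrix: {missing_ref[:5]}")
    ordered_genes = list(order["gene"])
    missing = [g for g in ordered_genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"genes in order missing from expression: {missing[:5]}")
    if len(ordered_genes) < 2 * half_window + 1:
        raise ValueError(
            f"gene order covers {len(ordered_genes)} genes; need >= {2 * half_window + 1}"
        )

    log = expr.to_log2()
    X = log.data.loc[ordered_genes].to_numpy(dtype=float).T  # cells x genes
    ref_idx = [log.sample_ids.index(c) for c in refs]
    E = X - X[ref_idx].mean(axis=0)
    if clip:
        E = np.clip(E, -clip, clip)

    profile = np.empty_like(E)
    chroms = order["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        profile[:, cols] = _windowed_mean(E[:, cols], half_window)

    return pd.DataFrame(profile, index=log.sample_ids, columns=ordered_genes)


def call_gain_loss(values, threshold: float = 0.2):
    """Classify copy-number values as gain (> +threshold), loss
    (< -threshold) or neutral.

    The symmetric threshold reads the published gain rule literally and
    mirrors it for losses.
    """
    arr = np.asarray(values, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("copy-number values must be finite")
    calls = np.full(arr.shape, "neutral", dtype=object)
    calls[arr > threshold] = "gain"
    calls[arr < -threshold] = "loss"
    if isinstance(values, pd.Series):
        return pd.Series(calls, index=values.index)
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(calls, index=values.index, columns=values.columns)
    return calls
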