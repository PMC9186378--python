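"""Per-sample gene-set scoring and the immune hot/cold phenotype.

The workhorse is single-sample GSEA (ssGSEA): per sample, genes are
ranked by expression and a weighted Kolmogorov-Smirnov-like running sum
accumulates the difference between the in-set and out-of-set cumulative
distributions; the score is the integral (sum) of that difference over
all gene positions, with in-set genes weighted by rank^alpha
(alpha = 0.25 by default, the GSVA ssgsea convention). Scoring the
four-chemokine set {CXCL9, CXCL10, CXCL11, CCL5} and splitting cohorts
at the median score yields the immune hot/cold phenotype; the
fold-change statistic contrasts mean immune-related scores between the
two groups; TMB is mutations per megabase.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matrix import ExpressionMatrix

__all__ = [
    "CHEMOKINE_SET",
    "ssgsea",
    "hot_cold_split",
    "signature_fold_change",
    "tmb",
]

#: The four-chemokine grade set defining the hot/cold axis.
CHEMOKINE_SET = {"chemokine4": ["CXCL9", "CXCL10", "CXCL11", "CCL5"]}


def _ssgsea_one(ranks: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Running-sum enrichment of one set in one sample.

    ``ranks`` are expression ranks (highest expression = largest rank,
    average ranks for ties); the sum runs over positions in decreasing
    rank order.
    """
    order = np.argsort(-ranks, kind="stable")
    in_ord = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(in_ord, w, 0.0)
    denom_in = w_in.sum()
    n_out = int((~in_ord).sum())
    cum_in = np.cumsum(w_in) / denom_in if denom_in > 0 else np.zeros_like(w_in)
    if n_out:
        cum_out = np.cumsum(np.where(in_ord, 0.0, 1.0)) / n_out
    else:
        cum_out = np.zeros_like(w_in)  # set covers every gene: out-term vanishes
    return float(np.sum(cum_in - cum_out))


def ssgsea(
    expr: ExpressionMatrix,
    sets: dict[str, list[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA scores for each gene set in each sample.

    Parameters
    ----------
    expr:
        Expression matrix (any monotone scale; only within-sample ranks
        are used).
    sets:
        Mapping set name -> gene ids; each must overlap the matrix genes.
    alpha:
        Rank-weighting exponent for in-set genes.
    normalize:
        If True, divide all scores by the global max - min across the
        returned score matrix (the GSVA ssgsea normalization).

    Returns
    -------
    DataFrame of samples x sets.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    masks = {}
    for name, genes in sets.items():
        if len(set(genes)) != len(list(genes)):
            raise ValueError(f"gene set {name!r} contains duplicate ids")
        idx = [gene_index[g] for g in genes if g in gene_index]
        if not idx:
            raise ValueError(f"gene set {name!r} has no genes in the expression matrix")
        m = np.zeros(expr.n_genes, dtype=bool)
        m[idx] = True
        masks[name] = m

    X = expr.values
    out = np.empty((expr.n_samples, len(masks)))
    for j in range(expr.n_samples):
        ranks = rankdata(X[:, j])  # average ranks; largest expression -> largest rank
        for k, mask in enumerate(masks.values()):
            out[j, k] = _ssgsea_one(ranks, mask, alpha)

    scores = pd.DataFrame(out, index=expr.sample_ids, columns=list(masks))
    if normalize:
        rng = float(out.max() - out.min())
        if rng > 0:
            scores = scores / rng
    return scores


def hot_cold_split(scores: pd.Series) -> pd.Series:
    """Median split of one score column into hot (above) / cold (at or below).

    Ties at the exact median are labelled cold, which is deterministic and
    conservative toward calling a tumor immune hot.
    """
    s = pd.Series(scores).astype(float)
    if len(s) < 2:
        raise ValueError("need at least 2 samples to split")
    if s.nunique() == 1:
        raise ValueError("all scores identical; no median split possible")
    med = float(s.median())
    return pd.Series(np.where(s > med, "hot", "cold"), index=s.index, name="phenotype")


def signature_fold_change(
    sig_scores: pd.DataFrame,
    labels: pd.Series,
) -> pd.Series:
    """Hot-minus-cold difference of mean scores, per signature column.

    Fold-Change = (1/n1) sum of scores over hot samples − (1/n2) sum over
    cold samples, computed column-wise. ``sig_scores`` may carry immune
    cell fractions and/or signature ssGSEA scores (or their sum as an
    immune-related score column); ``labels`` holds 'hot'/'cold'.
    """
    common = sig_scores.index.intersection(labels.index)
    if len(common) < len(sig_scores):
        missing = sig_scores.index.difference(labels.index)
        raise ValueError(f"samples without hot/cold label: {list(missing[:5])}")
    lab = labels.loc[common]
    hot = sig_scores.loc[common[lab == "hot"]]
    cold = sig_scores.loc[common[lab == "cold"]]
    if hot.empty or cold.empty:
        raise ValueError("both hot and cold groups must be non-empty")
    return hot.mean(axis=0) - cold.mean(axis=0)


def tmb(nonsynonymous_mutation_count: float, megabases_covered: float) -> float:
    """Tumor mutational burden: non-synonymous mutations per megabase."""
    if nonsynonymous_mutation_count < 0:
        raise ValueError("mutation count must be non-negative")
    if megabases_covered <= 0:
        raise ValueError("megabases_covered must be positive")
    return nonsynonymous_mutation_count / megabases_covered
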