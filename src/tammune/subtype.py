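"""Consensus clustering and the two-step immune subtype classifier.

Tumors are subtyped in two resampled clustering passes. Step 1 consensus-
clusters samples on their 22 immune-cell fractions into k=2 groups; the
group with the higher mean summed immune fraction is subtype A (immune
infiltrated), the other B. Step 2 consensus-clusters the A samples only,
on z-scored expression of the early TAMM-differentiation signature, into
k=3 groups ordered A1/A2/A3 by decreasing mean immune fraction. Consensus
clustering follows the Monti resampling scheme: repeated subsampling,
hierarchical clustering (Euclidean distance, Ward linkage on unsquared
distances), and aggregation of co-clustering frequencies into a consensus
matrix that is itself hierarchically partitioned. Survival differences
between two groups use the log-rank test with Kaplan-Meier summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionMatrix
from .synth import MALIGNANT

__all__ = [
    "ConsensusResult",
    "consensus_cluster",
    "two_step_subtype",
    "logrank",
    "km_curve",
]


@dataclass
class ConsensusResult:
    """Consensus clustering outcome for one k."""

    k: int
    consensus_matrix: pd.DataFrame
    labels: pd.Series               # cluster ids 1..k
    pac_score: float                # proportion of ambiguous clustering


def _ward_unsquared_labels(dist_condensed: np.ndarray, k: int) -> np.ndarray:
    """Cut a Ward tree built on unsquared distances into k clusters.

    scipy's ``ward`` implements the ward.D2 variant (squares its input);
    feeding it sqrt(d) therefore reproduces the merge tree of Ward on the
    raw distances d (the hclust ward.D convention the analysis assumes).
    """
    Z = linkage(np.sqrt(dist_condensed), method="ward")
    return fcluster(Z, t=k, criterion="maxclust")


def consensus_cluster(
    features: pd.DataFrame,
    k: int,
    reps: int = 1000,
    subsample_fraction: float = 0.8,
    seed: int = 0,
) -> ConsensusResult:
    """Monti consensus clustering of samples (rows) into k groups.

    For each repetition a fraction of samples is drawn without
    replacement and Ward-clustered on Euclidean distances; consensus[i,j]
    is the fraction of co-drawn repetitions in which i and j co-cluster.
    Final labels come from Ward clustering of 1 - consensus. PAC is the
    fraction of off-diagonal consensus entries strictly between 0.1 and
    0.9 (lower = cleaner structure).
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if k < 2 or k > n // 2:
        raise ValueError(f"k must lie in [2, n_samples/2], got k={k} for n={n}")
    if np.allclose(X, X[0], atol=0.0):
        raise ValueError("zero-variance input: all samples identical")

    rng = np.random.default_rng(seed)
    m = max(k, int(round(subsample_fraction * n)))
    co = np.zeros((n, n))
    together = np.zeros((n, n))

    for _ in range(reps):
        sub = np.sort(rng.choice(n, size=m, replace=False))
        d = pdist(X[sub], metric="euclidean")
        lab = _ward_unsquared_labels(d, k)
        together[np.ix_(sub, sub)] += 1.0
        same = lab[:, None] == lab[None, :]
        co[np.ix_(sub, sub)] += same

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(together > 0, co / np.maximum(together, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    final = _ward_unsquared_labels(squareform(1.0 - consensus, checks=False), k)

    tri = consensus[np.triu_indices(n, k=1)]
    pac = float(np.mean((tri > 0.1) & (tri < 0.9)))

    idx = features.index
    return ConsensusResult(
        k=k,
        consensus_matrix=pd.DataFrame(consensus, index=idx, columns=idx),
        labels=pd.Series(final, index=idx, name="cluster"),
        pac_score=pac,
    )


def _immune_fraction(fractions: pd.DataFrame) -> pd.Series:
    """Summed immune fraction per sample (non-immune compartments excluded)."""
    immune_cols = [c for c in fractions.columns if c != MALIGNANT]
    return fractions[immune_cols].sum(axis=1)


def two_step_subtype(
    fractions: pd.DataFrame,
    expr: ExpressionMatrix,
    early_genes: set[str] | list[str],
    seed: int = 0,
    reps: int = 200,
    subsample_fraction: float = 0.8,
    ab_labels: pd.Series | None = None,
) -> pd.Series:
    """Two-step classifier: immune fractions -> A/B, early signature -> A1/A2/A3.

    Returns a Series of labels in {A1, A2, A3, B} over all samples.
    ``ab_labels`` ('A'/'B' per sample) skips step 1 when the immune/cold
    partition is already known — step 2 depends only on the A samples.
    """
    samples = [s for s in fractions.index if s in set(expr.sample_ids)]
    if len(samples) != len(fractions) or len(samples) != expr.n_samples:
        raise ValueError("fractions and expression must share their sample ids")
    genes = [g for g in expr.gene_ids if g in set(early_genes)]
    if len(genes) < 2:
        raise ValueError("need >= 2 early-signature genes present in expression")

    imm = _immune_fraction(fractions.loc[samples])
    if ab_labels is not None:
        ab = ab_labels.loc[samples]
        a_samples = [s for s in samples if ab[s] == "A"]
        b_samples = [s for s in samples if ab[s] != "A"]
    else:
        # step 1: k=2 on the immune-cell fraction columns
        step1 = consensus_cluster(
            fractions.loc[samples], k=2, reps=reps,
            subsample_fraction=subsample_fraction, seed=seed,
        )
        means = imm.groupby(step1.labels).mean()
        a_cluster = int(means.idxmax())
        a_samples = [s for s in samples if step1.labels[s] == a_cluster]
        b_samples = [s for s in samples if step1.labels[s] != a_cluster]
    if not a_samples:
        raise ValueError("step 1 assigned no samples to the immune-infiltrated group")

    labels = pd.Series(index=pd.Index(samples), dtype=object, name="subtype")
    labels.loc[b_samples] = "B"

    # step 2: k=3 on z-scored early-signature expression of the A samples
    sub = expr.to_log2().data.loc[genes, a_samples].T  # samples x genes
    sd = sub.std(axis=0, ddof=0).replace(0, 1.0)
    z = (sub - sub.mean(axis=0)) / sd
    step2 = consensus_cluster(
        z, k=3, reps=reps, subsample_fraction=subsample_fraction, seed=seed + 1,
    )
    lab2 = step2.labels
    sizes = lab2.value_counts()
    if (sizes < 2).any():
        # undersized cluster: merge its members into the nearest big cluster
        warnings.warn("step-2 cluster with < 2 samples; merging into nearest cluster")
        small = sizes[sizes < 2].index
        big = sizes[sizes >= 2].index
        cent = {c: z.loc[lab2 == c].mean(axis=0).to_numpy() for c in big}
        for s in lab2.index[lab2.isin(small)]:
            v = z.loc[s].to_numpy()
            lab2[s] = min(cent, key=lambda c: np.linalg.norm(v - cent[c]))

    # order clusters A1 > A2 > A3 by decreasing mean immune fraction
    order = (
        imm.loc[a_samples].groupby(lab2).mean().sort_values(ascending=False).index
    )
    rename = {c: f"A{i + 1}" for i, c in enumerate(order)}
    labels.loc[a_samples] = lab2.map(rename)
    return labels


def logrank(
    surv: pd.DataFrame, labels: pd.Series
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi_square, p_value).

    ``surv`` needs columns ``time`` (> 0) and ``event`` (0/1); ``labels``
    assigns each sample to one of exactly two groups.
    """
    common = surv.index.intersection(labels.index)
    groups = pd.Series(labels).loc[common]
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError(f"need exactly 2 non-empty groups, got {len(names)}")
    t = surv.loc[common, "time"].astype(float)
    e = surv.loc[common, "event"].astype(int)
    if (t <= 0).any() or not np.isfinite(t).all():
        raise ValueError("survival times must be positive and finite")
    if e.sum() == 0:
        raise ValueError("need at least one event")
    m0 = groups == names[0]
    res = logrank_test(t[m0], t[~m0], event_observed_A=e[m0], event_observed_B=e[~m0])
    return float(res.test_statistic), float(res.p_value)


def km_curve(surv: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier step function as a (time, survival) table."""
    kmf = KaplanMeierFitter()
    kmf.fit(surv["time"].astype(float), surv["event"].astype(int))
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )
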