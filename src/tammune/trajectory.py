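"""Diffusion-map embedding and pseudotime ordering of single cells.

Differentiating cells are modelled as following noisy diffusion-like
dynamics: a Gaussian kernel with locally adaptive bandwidth (distance to
the ``n_neighbors/2``-th neighbor) on the kNN graph defines a Markov
transition operator over cells; its leading non-trivial right
eigenvectors, scaled by their eigenvalues, embed the cells so that
diffusion proximity becomes Euclidean proximity. Pseudotime is the
Euclidean distance from a chosen root cell in that embedding, rescaled
to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata, spearmanr
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix
from .preprocess import benjamini_hochberg

__all__ = [
    "DiffusionEmbedding",
    "diffusion_map",
    "pseudotime",
    "expression_along_pseudotime",
]


@dataclass
class DiffusionEmbedding:
    """Diffusion components (cells x n_components) and their eigenvalues."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray

    @property
    def cell_ids(self) -> list[str]:
        return list(self.coordinates.index)


def diffusion_map(
    expr: ExpressionMatrix,
    n_components: int = 3,
    n_neighbors: int = 15,
) -> DiffusionEmbedding:
    """Diffusion-map embedding of cells from log-scale expression.

    Cells are rows of the transition operator; the trivial constant
    eigenvector (eigenvalue 1) is dropped and the next ``n_components``
    right eigenvectors, scaled by their eigenvalues, are returned in
    decreasing-eigenvalue order. Raises if the kNN graph is disconnected.
    """
    if not expr.is_log:
        expr = expr.to_log2()
    X = expr.values.T  # cells x genes
    n = X.shape[0]
    if n < n_neighbors + 1:
        raise ValueError(f"need more than n_neighbors={n_neighbors} cells, got {n}")

    # query a few extra neighbors and keep everything within the k-th
    # neighbor distance, so ties (e.g. duplicated cells) enter the graph
    # symmetrically instead of by argsort order
    k_query = min(n - 1, n_neighbors + 8)
    nn = NearestNeighbors(n_neighbors=k_query + 1).fit(X)
    dist, idx = nn.kneighbors(X)
    # with duplicated cells the self match need not sit at position 0:
    # identify it by index, not by rank
    valid = idx != np.arange(n)[:, None]
    dist_valid = np.where(valid, dist, np.inf)
    dist_sorted = np.sort(dist_valid, axis=1)
    radius = dist_sorted[:, n_neighbors - 1]
    keep = valid & (dist <= radius[:, None] * (1 + 1e-12))

    # locally adaptive bandwidth: distance to the (n_neighbors/2)-th neighbor
    k_local = max(1, n_neighbors // 2)
    sigma = dist_sorted[:, k_local - 1].copy()
    sigma[sigma == 0] = np.min(sigma[sigma > 0]) if (sigma > 0).any() else 1.0

    rows = np.repeat(np.arange(n), dist.shape[1])[keep.ravel()]
    cols = idx.ravel()[keep.ravel()]
    d2 = (dist.ravel()[keep.ravel()]) ** 2
    s2 = sigma[rows] * sigma[cols]  # geometric-mean local scales
    w = np.exp(-d2 / (2.0 * s2))
    W = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)  # symmetrize the kNN kernel
    W = W + sparse.identity(n, format="csr")

    n_comp_graph, _ = connected_components(W, directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"kNN graph has {n_comp_graph} components; increase n_neighbors"
        )

    # row-normalized transition operator; eigendecompose the symmetric
    # conjugate D^-1/2 W D^-1/2 for stable, real spectra
    deg = np.asarray(W.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    S = sparse.diags(d_inv_sqrt) @ W @ sparse.diags(d_inv_sqrt)
    S = np.asarray(S.todense())
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # right eigenvectors of the transition matrix P = D^-1 W
    psi = evecs * d_inv_sqrt[:, None]
    lam = evals[1 : n_components + 1]
    comps = psi[:, 1 : n_components + 1] * lam[None, :]
    # sign convention: first cell non-negative on each component
    for k in range(comps.shape[1]):
        anchor = comps[np.argmax(np.abs(comps[:, k])), k]
        if anchor < 0:
            comps[:, k] = -comps[:, k]

    coords = pd.DataFrame(
        comps,
        index=expr.sample_ids,
        columns=[f"DC{i + 1}" for i in range(comps.shape[1])],
    )
    return DiffusionEmbedding(coordinates=coords, eigenvalues=lam)


def pseudotime(emb: DiffusionEmbedding, root: str) -> pd.Series:
    """Per-cell pseudotime: diffusion distance from the root, min-max
    rescaled to [0, 1] (root = 0).

    Distances are taken in accumulated-diffusion coordinates — each
    component rescaled from its single-step weight lambda to
    lambda/(1 - lambda), the sum over all walk lengths — so slow modes
    (the differentiation axis) dominate transient geometric modes.
    """
    if root not in emb.coordinates.index:
        raise KeyError(f"root cell {root!r} not in embedding")
    lam = np.clip(emb.eigenvalues, None, 1.0 - 1e-12)
    scale = 1.0 / (1.0 - lam)  # lambda*psi -> (lambda/(1-lambda))*psi
    C = emb.coordinates.to_numpy() * scale[None, :]
    r = C[emb.coordinates.index.get_loc(root)]
    d = np.linalg.norm(C - r, axis=1)
    if d.max() > 0:
        d = d / d.max()
    return pd.Series(d, index=emb.coordinates.index, name="pseudotime")


def expression_along_pseudotime(
    expr: ExpressionMatrix,
    pt: pd.Series,
    gene_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each gene's expression with pseudotime.

    Returns a DataFrame indexed by gene with columns ``rho``, ``p``,
    ``fdr`` and ``constant`` (True when the gene never varies, in which
    case rho is reported as 0 with p = 1).
    """
    genes = list(gene_ids) if gene_ids is not None else expr.gene_ids
    missing = [g for g in genes if g not in set(expr.gene_ids)]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    cells = [c for c in expr.sample_ids if c in set(pt.index)]
    if len(cells) < 3:
        raise ValueError("need at least 3 cells shared between expression and pseudotime")

    t = pt.loc[cells].to_numpy(dtype=float)
    X = expr.data.loc[genes, cells].to_numpy(dtype=float)
    t_rank = rankdata(t)

    rho = np.zeros(len(genes))
    p = np.ones(len(genes))
    const = np.zeros(len(genes), dtype=bool)
    for i in range(len(genes)):
        if np.all(X[i] == X[i, 0]):
            const[i] = True
            continue
        r, pv = spearmanr(X[i], t_rank)
        rho[i], p[i] = float(r), float(pv)
    return pd.DataFrame(
        {"rho": rho, "p": p, "fdr": benjamini_hochberg(p), "constant": const},
        index=genes,
    )
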