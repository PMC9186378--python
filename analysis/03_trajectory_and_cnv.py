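#!/usr/bin/env python
"""Order the cells along their differentiation trajectory and estimate
copy-number profiles.

The diffusion map embeds the QC'd, library-normalized cells; pseudotime
is diffusion distance from the earliest (lowest-latent-time) cell. The
101-gene windowed estimator then scores relative copy number against the
non-aberrant reference cells and calls the planted gain.
"""

from pathlib import Path

import pandas as pd
from scipy.stats import spearmanr

from tammune import cnv, preprocess, trajectory
from tammune import io as tio

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"


def main() -> None:
    filtered = tio.read_expression_tsv(BASE / "sc_filtered.tsv")
    truth = pd.read_csv(DATA / "sc_cell_truth.tsv", sep="\t", index_col=0)
    latent = truth.loc[filtered.sample_ids, "latent_time"]

    norm = preprocess.normalize_counts(filtered).to_log2()
    # order cells on the differentiation signature derived in step 02, so
    # orthogonal structure (the planted copy-number segment) does not
    # dominate the embedding — the usual ordering-gene selection step
    signatures = tio.read_gmt(BASE / "signatures.gmt")
    ordering_genes = sorted(set(signatures["early"]) | set(signatures["late"]))
    emb = trajectory.diffusion_map(
        norm.subset(genes=ordering_genes), n_components=3, n_neighbors=15
    )
    pt = trajectory.pseudotime(emb, latent.idxmin())
    table = emb.coordinates.copy()
    table["pseudotime"] = pt
    table.to_csv(BASE / "sc_trajectory.tsv", sep="\t", index_label="cell")
    rho = spearmanr(pt, latent)[0]
    print(f"pseudotime vs planted latent time: Spearman rho = {rho:.3f} "
          f"({len(pt)} cells)")

    markers = tio.read_gmt(DATA / "sc_marker_truth.gmt")
    trends = trajectory.expression_along_pseudotime(
        norm, pt, markers["early"] + markers["late"]
    )
    trends.to_csv(BASE / "sc_marker_trends.tsv", sep="\t", index_label="gene")
    print(f"marker trends along pseudotime: early mean rho = "
          f"{trends.loc[markers['early'], 'rho'].mean():.2f}, late mean rho = "
          f"{trends.loc[markers['late'], 'rho'].mean():.2f}")

    # CNV against the cells that do not carry the planted gain
    raw = tio.read_expression_tsv(DATA / "sc_counts.tsv")
    cnv_cells = (DATA / "sc_cnv_cells.txt").read_text().split()
    refs = [c for c in raw.sample_ids if c not in set(cnv_cells)]
    order = tio.read_gene_order(DATA / "sc_gene_order.bed")
    profile = cnv.infer_cnv_profile(raw, refs, order, half_window=50)
    profile.to_csv(BASE / "sc_cnv_profile.tsv", sep="\t", index_label="cell")

    tumor_mean = profile.loc[cnv_cells].mean(axis=0)
    calls = cnv.call_gain_loss(tumor_mean, threshold=0.2)
    called = calls.iloc[150:200]  # segment interior with full window support
    print(f"planted gain: {100 * (called == 'gain').mean():.0f}% of interior "
          f"positions called gain; mean log2 ratio "
          f"{tumor_mean.iloc[150:200].mean():.2f}")


if __name__ == "__main__":
    main()
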