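#!/usr/bin/env python
"""Generate the three synthetic study cohorts with their ground truth.

Emulates the study's inputs: a single-cell differentiation cohort with a
planted copy-number segment, a bulk tumor cohort with the planted
A1/A2/A3/B immune structure, hot/cold phenotype, survival and ICB
response labels, and an interaction network with a planted hub module.
Everything downstream (02-06) reads from results/data/.
"""

from pathlib import Path

import pandas as pd

from tammune import io as tio
from tammune import synth

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    sc = synth.gen_sc_cohort(
        synth.ScSimConfig(n_cells=500, n_genes=600, noise_sd=0.2,
                          cnv_segments=[(100, 250, 2.0)], seed=SEED)
    )
    tio.write_expression_tsv(sc.counts, OUT / "sc_counts.tsv")
    pd.DataFrame({"latent_time": sc.latent_time, "subcluster": sc.subcluster}).to_csv(
        OUT / "sc_cell_truth.tsv", sep="\t", index_label="cell"
    )
    tio.write_gmt({"early": sc.early_genes, "late": sc.late_genes},
                  OUT / "sc_marker_truth.gmt")
    tio.write_gene_order(sc.gene_order, OUT / "sc_gene_order.bed")
    (OUT / "sc_cnv_cells.txt").write_text("\n".join(sc.cnv_cells) + "\n")
    sc.cnv_profile.to_csv(OUT / "sc_cnv_truth.tsv", sep="\t", header=True)
    print(f"single-cell cohort: {sc.counts.n_genes} genes x {sc.counts.n_samples} "
          f"cells, {len(sc.cnv_cells)} cells carry the planted 150-gene gain")

    bulk = synth.gen_bulk_cohort(
        synth.BulkSimConfig(n_samples=200, n_genes=300, noise_sd=0.2,
                            plant_a_subtypes=3, seed=SEED + 1)
    )
    tio.write_expression_tsv(bulk.expression, OUT / "bulk_expression.tsv")
    bulk.basis.to_csv(OUT / "bulk_basis.tsv", sep="\t", index_label="gene")
    bulk.true_fractions.to_csv(OUT / "bulk_fractions_truth.tsv", sep="\t",
                               index_label="sample")
    bulk.hot_labels.to_csv(OUT / "bulk_hot_truth.tsv", sep="\t", header=True)
    bulk.survival.to_csv(OUT / "bulk_survival.tsv", sep="\t", index_label="sample")
    bulk.response.to_csv(OUT / "bulk_response.tsv", sep="\t", header=True)
    bulk.subtypes.to_csv(OUT / "bulk_subtype_truth.tsv", sep="\t", header=True)
    tio.write_gmt({"early": bulk.early_genes}, OUT / "bulk_early_signature.gmt")
    print(f"bulk cohort: {bulk.expression.n_samples} samples, planted subtype "
          f"sizes {bulk.subtypes.value_counts().to_dict()}")

    g, module = synth.gen_ppi(synth.GraphSimConfig(seed=SEED + 2))
    tio.write_edge_list(g, OUT / "ppi_edges.tsv")
    (OUT / "ppi_module_truth.txt").write_text("\n".join(module) + "\n")
    print(f"interaction network: {g.number_of_nodes()} nodes, "
          f"{g.number_of_edges()} edges, planted module of {len(module)}")


if __name__ == "__main__":
    main()
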