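#!/usr/bin/env python
"""QC-filter the single-cell cohort and derive the TAMM differentiation
signatures.

Cells are filtered on detected-gene count and mitochondrial fraction,
genes on detection support; the early (monocyte, C1) vs late (mature
macrophage, C0) archetypes are then contrasted by Wilcoxon rank-sum DE
and thresholded at |log2FC| > 1.3, FDR < 0.05 into the early/late
signatures, which are compared against the planted marker truth.
"""

from pathlib import Path

import pandas as pd

from tammune import io as tio
from tammune import preprocess

BASE = Path(__file__).resolve().parent.parent / "results"
DATA = BASE / "data"


def main() -> None:
    raw = tio.read_expression_tsv(DATA / "sc_counts.tsv")
    truth = pd.read_csv(DATA / "sc_cell_truth.tsv", sep="\t", index_col=0)
    markers = tio.read_gmt(DATA / "sc_marker_truth.gmt")

    thr = preprocess.QcThresholds(min_cells_per_gene=3, min_genes_per_cell=100,
                                  max_genes_per_cell=600, max_mito_fraction=0.10)
    filtered, report = preprocess.qc_filter(raw, thr)
    tio.write_expression_tsv(filtered, BASE / "sc_filtered.tsv")
    print(f"QC: removed {report.n_genes_removed} genes and "
          f"{report.n_cells_removed} cells -> "
          f"{report.n_genes_kept} x {report.n_cells_kept}")

    c1 = [c for c in filtered.sample_ids if truth.loc[c, "subcluster"] == "C1"]
    c0 = [c for c in filtered.sample_ids if truth.loc[c, "subcluster"] == "C0"]
    de = preprocess.wilcoxon_de(filtered, c1, c0)
    de.to_csv(BASE / "sc_de_c1_vs_c0.tsv", sep="\t", index_label="gene")

    sig = preprocess.split_signatures(de, lfc_cut=1.3, fdr_cut=0.05)
    tio.write_gmt({"early": sorted(sig.early_genes), "late": sorted(sig.late_genes)},
                  BASE / "signatures.gmt")

    for name, found, planted in (
        ("early", sig.early_genes, markers["early"]),
        ("late", sig.late_genes, markers["late"]),
    ):
        hit = len(set(found) & set(planted))
        print(f"{name} signature: {len(found)} genes called, "
              f"{hit}/{len(planted)} planted markers recovered "
              f"({100 * hit / len(planted):.0f}%)")


if __name__ == "__main__":
    main()
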