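"""Plain-text I/O: expression TSV, GMT gene sets, edge lists, BED-like gene orders.

All pipeline artifacts are tab-separated text so that runs are diffable and
portable. Expression tables have genes on rows (first column = gene id,
header row = sample ids), matching the layout the generators emit.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .matrix import ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_gene_order",
    "write_gene_order",
]


def read_expression_tsv(path: str | Path, is_log: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, is_log=is_log)


def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list}; the description field is dropped."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read a 2-column TSV (or 3-column SIF `node relation node`) into a simple graph."""
    g = nx.Graph()
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 2:
            u, v = fields
        elif len(fields) == 3:  # SIF: source relation target
            u, _, v = fields
        else:
            raise ValueError(f"expected 2 or 3 tab-separated fields: {line!r}")
        if u != v:
            g.add_edge(u, v)
    return g


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(tuple(sorted(e)) for e in g.edges())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_gene_order(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV (chrom, start, end, gene) sorted by genomic location."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"], comment="#"
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def write_gene_order(order: pd.DataFrame, path: str | Path) -> None:
    order[["chrom", "start", "end", "gene"]].to_csv(path, sep="\t", header=False, index=False)
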