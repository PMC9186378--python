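"""Core data container: a genes x samples expression matrix.

Every stage of the pipeline exchanges :class:`ExpressionMatrix` objects —
raw single-cell counts, bulk mixtures, and log-transformed views alike.
The container is a thin, validated wrapper around a pandas DataFrame with
genes on the rows and cells/samples on the columns, plus a flag recording
whether the values are on log2 scale (and, if so, which pseudocount was
used), so downstream operations can demand the scale they need instead of
guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with an explicit scale flag.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with one column per cell/sample.
    is_log:
        True if values are ``log2(x + pseudocount)`` transformed.
    pseudocount:
        Pseudocount used for the log transform (only meaningful when
        ``is_log`` is True).
    """

    data: pd.DataFrame
    is_log: bool = False
    pseudocount: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if not self.is_log and values.size and (values < 0).any():
            raise ValueError("non-log expression values must be >= 0")

    # ------------------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    # ------------------------------------------------------------------
    def to_log2(self, pseudocount: float = 1.0) -> "ExpressionMatrix":
        """Return a log2(x + pseudocount) view; no-op if already log scale."""
        if self.is_log:
            return self
        return ExpressionMatrix(
            np.log2(self.data + pseudocount),
            is_log=True,
            pseudocount=pseudocount,
            meta=dict(self.meta),
        )

    def to_linear(self) -> "ExpressionMatrix":
        """Invert the log2 transform; no-op if already linear scale."""
        if not self.is_log:
            return self
        return ExpressionMatrix(
            np.exp2(self.data) - self.pseudocount,
            is_log=False,
            meta=dict(self.meta),
        )

    def subset(
        self,
        genes: list[str] | None = None,
        samples: list[str] | None = None,
    ) -> "ExpressionMatrix":
        """Restrict to the given genes/samples, preserving current order of the request."""
        df = self.data
        if genes is not None:
            missing = [g for g in genes if g not in df.index]
            if missing:
                raise KeyError(f"genes not in matrix: {missing[:5]}")
            df = df.loc[genes]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:5]}")
            df = df[samples]
        return ExpressionMatrix(df.copy(), self.is_log, self.pseudocount, dict(self.meta))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        scale = f"log2(+{self.pseudocount:g})" if self.is_log else "linear"
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, {scale})"
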