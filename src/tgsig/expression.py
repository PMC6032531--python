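"""Gene-by-sample expression container with response labels.

The matrix is stored genes x samples (the orientation of the on-disk TSV);
:attr:`ExpressionMatrix.X` exposes the samples x genes view used by the
scikit-learn-style estimators. Values are log2-scale expression by
convention; linear-scale input can be converted on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._exceptions import DataError, MissingGeneError

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
VALID_LABELS = frozenset({RESPONDER, NON_RESPONDER})


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) plus per-sample group labels.

    Parameters
    ----------
    data:
        DataFrame indexed by gene id with one column per sample id.
    labels:
        Series mapping sample id -> ``"responder"`` / ``"non_responder"``.
        Must cover every sample column; both groups must be non-empty.
    """

    data: pd.DataFrame
    labels: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise DataError("duplicate gene identifiers in expression matrix")
        if self.data.columns.has_duplicates:
            raise DataError("duplicate sample identifiers in expression matrix")
        self.labels = pd.Series(self.labels)
        missing = set(self.data.columns) - set(self.labels.index)
        if missing:
            raise DataError(f"samples without a label: {sorted(missing)}")
        self.labels = self.labels.reindex(self.data.columns)
        bad = set(self.labels.unique()) - VALID_LABELS
        if bad:
            raise DataError(f"unknown labels {sorted(bad)}; expected {sorted(VALID_LABELS)}")
        for group in VALID_LABELS:
            if not (self.labels == group).any():
                raise DataError(f"group {group!r} has no samples")

    # -- accessors -----------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        """Samples x genes value matrix (the estimator orientation)."""
        return self.data.to_numpy(dtype=float).T

    @property
    def y(self) -> np.ndarray:
        """Label vector aligned with :attr:`X` rows."""
        return self.labels.to_numpy()

    def group_samples(self, group: str) -> list[str]:
        if group not in VALID_LABELS:
            raise DataError(f"unknown group {group!r}")
        return list(self.labels.index[self.labels == group])

    def group_values(self, group: str) -> pd.DataFrame:
        return self.data[self.group_samples(group)]

    def restrict(self, genes: list[str]) -> "ExpressionMatrix":
        """Sub-matrix on ``genes`` (order preserved); missing genes raise."""
        absent = [g for g in genes if g not in self.data.index]
        if absent:
            raise MissingGeneError(f"genes absent from expression matrix: {absent}")
        return ExpressionMatrix(self.data.loc[list(genes)], self.labels.copy())

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, expr_path: str | Path, labels_path: str | Path | None = None) -> None:
        df = self.data.copy()
        df.index.name = "gene_id"
        df.to_csv(expr_path, sep="\t")
        if labels_path is not None:
            lab = self.labels.rename("label").rename_axis("sample_id")
            lab.to_csv(labels_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        expr_path: str | Path,
        labels_path: str | Path,
        linear_input: bool = False,
    ) -> "ExpressionMatrix":
        """Load an expression TSV (first column gene id) and a labels TSV.

        With ``linear_input=True`` values are log2-transformed on load;
        zero or negative values are rejected because they have no log2
        fold-change interpretation.
        """
        data = pd.read_csv(expr_path, sep="\t", index_col=0)
        labels = read_labels(labels_path)
        if linear_input:
            values = data.to_numpy(dtype=float)
            if (values <= 0).any():
                raise DataError("linear-scale input contains non-positive values")
            data = pd.DataFrame(np.log2(values), index=data.index, columns=data.columns)
        return cls(data, labels)


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column sample/label TSV into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(str)
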