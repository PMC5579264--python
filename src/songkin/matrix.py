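"""Labeled symmetric matrices.

The analysis passes every pairwise quantity — acoustic dissimilarity between
phrases or individuals, genetic relatedness or distance, binary kin designs —
through the same container: an ordered set of labels plus a symmetric value
matrix.  The diagonal carries no information (self-dyads are excluded from all
statistics) and is kept at a fixed conventional value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SquareMatrix", "normalize01"]

_SYM_ATOL = 1e-12


@dataclass(frozen=True)
class SquareMatrix:
    """Symmetric matrix over an ordered label set.

    Parameters
    ----------
    labels
        Ordered, unique labels (one per row/column).
    values
        Square, symmetric ``(n, n)`` float array.
    diagonal
        Conventional diagonal value (0 for distances, 1 for similarities);
        informational only — the diagonal never enters any statistic.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    diagonal: float = 0.0

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"values must be square, got shape {v.shape}")
        if v.shape[0] != len(labels):
            raise ValueError(
                f"{len(labels)} labels for a {v.shape[0]}x{v.shape[1]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("labels must be unique")
        if not np.allclose(v, v.T, atol=_SYM_ATOL, rtol=0.0):
            raise ValueError("matrix is not symmetric (atol=1e-12)")
        v = 0.5 * (v + v.T)  # exact symmetry for downstream equality checks
        np.fill_diagonal(v, self.diagonal)
        v.flags.writeable = False
        object.__setattr__(self, "values", v)

    # -- basic queries -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} not in matrix") from None

    def offdiag(self) -> np.ndarray:
        """Condensed upper-triangle (off-diagonal) values, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    # -- derived matrices --------------------------------------------------
    def submatrix(self, labels) -> "SquareMatrix":
        """Restrict (and reorder) to the given labels."""
        idx = [self.index_of(l) for l in labels]
        return SquareMatrix(tuple(labels), self.values[np.ix_(idx, idx)],
                            diagonal=self.diagonal)

    def with_values(self, values: np.ndarray, diagonal: float | None = None) -> "SquareMatrix":
        d = self.diagonal if diagonal is None else diagonal
        return SquareMatrix(self.labels, values, diagonal=d)

    # -- IO ----------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="label")

    @classmethod
    def from_csv(cls, path, diagonal: float = 0.0) -> "SquareMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        if list(df.index.astype(str)) != list(df.columns.astype(str)):
            raise ValueError(f"{path}: row and column labels disagree")
        return cls(tuple(df.columns.astype(str)), df.to_numpy(dtype=float),
                   diagonal=diagonal)


def normalize01(m: SquareMatrix) -> SquareMatrix:
    """Min–max rescale the off-diagonal entries to [0, 1].

    Matrix indices are rescaled so that the smallest off-diagonal entry maps
    to 0 and the largest to 1 before entering any correlation statistic.

    Raises
    ------
    ValueError
        If all off-diagonal entries are equal (the rescaling is undefined).
    """
    off = m.offdiag()
    lo, hi = float(off.min()), float(off.max())
    if hi - lo <= 0.0:
        raise ValueError("degenerate matrix: all off-diagonal values equal")
    v = (m.values - lo) / (hi - lo)
    np.fill_diagonal(v, m.diagonal)
    return m.with_values(v)
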