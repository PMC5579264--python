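"""Principal components with Kaiser retention, and dissimilarity matrices.

The acoustic parameter sets are reduced by unrotated PCA on the correlation
matrix, retaining components with eigenvalue > 1 (Kaiser criterion).  The
scores carried downstream are the retained *standardized* component scores
(unit variance — the regression-type scores statistical packages save by
default), which makes the subsequent Euclidean distances scale-free.
Varimax rotation is available as an option but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import SquareMatrix

__all__ = ["PCAResult", "pca_kaiser", "phrase_distance", "individual_mean_distance"]


@dataclass(frozen=True)
class PCAResult:
    """Retained-component summary of a correlation-matrix PCA."""

    loadings: pd.DataFrame          # variables x retained components
    scores: pd.DataFrame            # cases x retained components (unit variance)
    eigenvalues: np.ndarray = field(repr=False)   # all p eigenvalues, descending
    var_pct: np.ndarray = field(repr=False)       # % variance per component (all p)
    n_retained: int = 0

    @property
    def cum_var_pct(self) -> float:
        """Cumulative % of total variance explained by the retained components."""
        return float(self.var_pct[: self.n_retained].sum())

    def variance_table(self) -> pd.DataFrame:
        k = len(self.eigenvalues)
        return pd.DataFrame({
            "component": [f"PC{i}" for i in range(1, k + 1)],
            "eigenvalue": self.eigenvalues,
            "pct_variance": self.var_pct,
            "cum_pct_variance": np.cumsum(self.var_pct),
            "retained": [i < self.n_retained for i in range(k)],
        })


def _varimax(loadings: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    from statsmodels.multivariate.factor_rotation import rotate_factors
    rotated, T = rotate_factors(loadings, "varimax")
    return rotated, T


def pca_kaiser(X: pd.DataFrame, rotate: bool = False) -> PCAResult:
    """PCA on the correlation matrix, retaining eigenvalues > 1.

    Parameters
    ----------
    X
        Cases × variables numeric DataFrame (no missing values; more cases
        than variables; every variable non-constant).
    rotate
        Apply a varimax rotation to the retained loadings (scores rotated
        accordingly).  Off by default.
    """
    if X.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more cases than variables, got {X.shape[0]} x {X.shape[1]}")
    values = X.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("missing values are not supported")
    sd = values.std(axis=0, ddof=1)
    constant = [str(c) for c, s in zip(X.columns, sd) if s == 0]
    if constant:
        raise ValueError(f"constant variable(s): {', '.join(constant)}")
    Z = (values - values.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    retained = int(np.sum(eigval > 1.0))
    if retained == 0:
        raise ValueError("no eigenvalue exceeds 1; nothing to retain")
    V = eigvec[:, :retained]
    lam = eigval[:retained]
    loadings = V * np.sqrt(lam)
    scores = Z @ V / np.sqrt(lam)          # unit-variance component scores
    if rotate and retained > 1:
        loadings, T = _varimax(loadings)
        # keep scores consistent with the rotated loadings (orthogonal T)
        scores = scores @ T
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(loadings.shape[1]):
        jmax = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[jmax, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{i}" for i in range(1, retained + 1)]
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        eigenvalues=eigval,
        var_pct=100.0 * eigval / len(eigval),
        n_retained=retained,
    )


def phrase_distance(scores: pd.DataFrame) -> SquareMatrix:
    """Pairwise Euclidean distances between score rows (diagonal 0)."""
    if scores.shape[0] == 0:
        raise ValueError("empty score matrix")
    d = squareform(pdist(scores.to_numpy(dtype=float), metric="euclidean"))
    return SquareMatrix(tuple(str(i) for i in scores.index), d)


def individual_mean_distance(d: SquareMatrix, phrase_to_individual) -> SquareMatrix:
    """Average phrase–phrase distances into an individual-level matrix.

    Entry (i, j), i != j, is the mean of ``d`` over all phrase pairs with
    one phrase from individual i and one from j.  The diagonal is set to 0
    and excluded from every downstream statistic.  Individuals are ordered
    by first appearance among the phrase labels.
    """
    mapping = {str(k): str(v) for k, v in dict(phrase_to_individual).items()}
    unmapped = [l for l in d.labels if l not in mapping]
    if unmapped:
        raise ValueError(f"unmapped phrase id(s): {', '.join(unmapped[:5])}")
    individuals = list(dict.fromkeys(mapping[l] for l in d.labels))
    ix = {ind: i for i, ind in enumerate(individuals)}
    one_hot = np.zeros((d.n, len(individuals)))
    for r, label in enumerate(d.labels):
        one_hot[r, ix[mapping[label]]] = 1.0
    counts = one_hot.sum(axis=0)
    sums = one_hot.T @ d.values @ one_hot
    denom = np.outer(counts, counts)
    # within-individual cells are never used; avoid 0/0 on the diagonal
    np.fill_diagonal(denom, 1.0)
    mean = sums / denom
    np.fill_diagonal(mean, 0.0)
    mean = 0.5 * (mean + mean.T)
    return SquareMatrix(tuple(individuals), mean)
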