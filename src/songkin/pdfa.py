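"""Permuted discriminant function analysis (pDFA).

Tests whether a *test factor* (individual identity, or group membership)
structures the acoustic scores while respecting the non-independence
induced by a *control factor* (the song a phrase was extracted from, or
the individual).  Phrases are grouped into blocks = unique
(test level × control level) cells; a chorus song shared by several
individuals therefore contributes one block per participating singer.

Observed statistic: for each of ``n_selections`` random balanced
selections, each test level contributes a fixed quota of its blocks to the
training set; a linear discriminant is fit on the training phrases and the
percentage of correctly classified phrases is recorded separately for the
training phrases (training rate) and the held-out phrases (testing rate),
then averaged over selections.

Null distribution: test-level labels are permuted over blocks (each
phrase inherits its block's permuted label), and the averaged rates are
recomputed with fresh selections; ``p = (#null >= observed + 1) /
(n_permutations + 1)``, separately for the training and testing rates.
The null uses the same number of selections per permutation as the
observed statistic so the two are identically distributed under the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg as sla

__all__ = ["LinearDiscriminant", "PDFAConfig", "PDFAResult",
           "pdfa", "pdfa_by_sex", "pdfa_group"]

log = logging.getLogger(__name__)


class LinearDiscriminant:
    """Fisher discriminant with nearest-centroid classification.

    Axes are the generalized eigenvectors of the between-class scatter
    against the pooled within-class covariance, scaled so the projected
    within-class covariance is the identity; classification assigns a case
    to the nearest class centroid in that space (uniform priors).  A
    singular within-class covariance is ridge-regularized with a logged
    constant.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearDiscriminant":
        X = np.asarray(X, dtype=float)
        classes, y_ix = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise ValueError("need at least 2 classes")
        counts = np.bincount(y_ix)
        if counts.min() < 2:
            bad = classes[counts < 2]
            raise ValueError(f"classes with a single case: {list(bad)}")
        n, d = X.shape
        means = np.vstack([X[y_ix == k].mean(axis=0)
                           for k in range(classes.size)])
        grand = X.mean(axis=0)
        Sw = np.zeros((d, d))
        for k in range(classes.size):
            xc = X[y_ix == k] - means[k]
            Sw += xc.T @ xc
        Sw /= max(n - classes.size, 1)
        diff = means - grand
        Sb = (diff * counts[:, None]).T @ diff / n
        eps = self.ridge * max(np.trace(Sw) / d, 1.0)
        try:
            evals = np.linalg.eigvalsh(Sw)
            if evals.min() <= eps:
                raise np.linalg.LinAlgError
            w, V = sla.eigh(Sb, Sw)
        except np.linalg.LinAlgError:
            log.debug("within-class covariance singular; ridge %.3g added", eps)
            w, V = sla.eigh(Sb, Sw + eps * np.eye(d))
        order = np.argsort(w)[::-1][: min(classes.size - 1, d)]
        self.classes_ = classes
        self.axes_ = V[:, order]               # projected within-cov = I
        self.centroids_ = means @ self.axes_
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = np.asarray(X, dtype=float) @ self.axes_
        d2 = ((Z[:, None, :] - self.centroids_[None, :, :]) ** 2).sum(axis=2)
        return self.classes_[np.argmin(d2, axis=1)]

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


@dataclass(frozen=True)
class PDFAConfig:
    """Design and permutation settings for one pDFA.

    ``training_quota``: blocks per test level entering the training set;
    defaults to (minimum block count over test levels) − 1, floor 1, so
    every level always holds data out.
    """

    test_factor: str = "individual_id"
    control_factor: str = "song_id"
    n_selections: int = 100
    n_permutations: int = 1000
    n_selections_null: int | None = None    # None -> n_selections
    training_quota: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_selections < 1 or self.n_permutations < 1:
            raise ValueError("n_selections and n_permutations must be >= 1")
        if self.n_selections_null is not None and self.n_selections_null < 1:
            raise ValueError("n_selections_null must be >= 1")
        if self.training_quota is not None and self.training_quota < 1:
            raise ValueError("training_quota must be >= 1")


@dataclass(frozen=True)
class PDFAResult:
    training_rate: float        # %
    training_p: float
    testing_rate: float         # %
    testing_p: float
    chance_rate: float          # % = 100 / number of test levels
    n_levels: int
    n_blocks: int
    n_phrases: int
    config: PDFAConfig
    per_level_testing: pd.Series = field(default_factory=pd.Series, repr=False)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.testing_p <= alpha


def _block_structure(meta: pd.DataFrame, test: str, control: str):
    """Phrase -> block index, block -> test label, block members."""
    for col in (test, control):
        if col not in meta.columns:
            raise ValueError(f"factor column {col!r} missing from metadata")
    keys = list(zip(meta[test].astype(str), meta[control].astype(str)))
    blocks = list(dict.fromkeys(keys))
    block_ix = {k: i for i, k in enumerate(blocks)}
    phrase_block = np.array([block_ix[k] for k in keys])
    block_label = np.array([k[0] for k in blocks])
    return phrase_block, block_label


def _rates_once(X, labels, phrase_block, block_label, quota, rng):
    """One balanced selection: (training %, testing %, per-level test hits)."""
    levels = np.unique(block_label)
    train_blocks = []
    for lev in levels:
        cand = np.where(block_label == lev)[0]
        train_blocks.extend(rng.choice(cand, size=quota, replace=False))
    in_train = np.isin(phrase_block, train_blocks)
    model = LinearDiscriminant().fit(X[in_train], labels[in_train])
    pred_tr = model.predict(X[in_train])
    pred_te = model.predict(X[~in_train])
    tr = float(np.mean(pred_tr == labels[in_train]))
    te_hits = pred_te == labels[~in_train]
    te = float(np.mean(te_hits))
    return 100 * tr, 100 * te, labels[~in_train], te_hits


def _averaged_rates(X, labels, phrase_block, block_label, quota,
                    n_selections, rng, collect_levels=False):
    trs, tes = np.empty(n_selections), np.empty(n_selections)
    hits: dict[str, list] = {}
    for s in range(n_selections):
        tr, te, te_labels, te_hits = _rates_once(
            X, labels, phrase_block, block_label, quota, rng)
        trs[s], tes[s] = tr, te
        if collect_levels:
            for lab, hit in zip(te_labels, te_hits):
                hits.setdefault(lab, []).append(hit)
    per_level = (pd.Series({k: 100 * np.mean(v) for k, v in hits.items()})
                 .sort_index() if collect_levels else pd.Series(dtype=float))
    return float(trs.mean()), float(tes.mean()), per_level


def pdfa(scores, meta: pd.DataFrame, cfg: PDFAConfig) -> PDFAResult:
    """Permuted DFA of ``cfg.test_factor`` controlling for ``cfg.control_factor``.

    ``scores`` is a cases × variables array or DataFrame aligned with
    ``meta`` row-wise.  Deterministic under ``cfg.seed``.
    """
    X = scores.to_numpy(dtype=float) if hasattr(scores, "to_numpy") else \
        np.asarray(scores, dtype=float)
    if X.shape[0] != len(meta):
        raise ValueError("scores and metadata are not aligned")
    phrase_block, block_label = _block_structure(
        meta, cfg.test_factor, cfg.control_factor)
    levels, level_counts = np.unique(block_label, return_counts=True)
    single = levels[level_counts < 2]
    if single.size:
        raise ValueError(
            f"test level(s) with a single control level (no held-out data "
            f"possible): {', '.join(map(str, single))}")
    quota = cfg.training_quota
    if quota is None:
        quota = max(int(level_counts.min()) - 1, 1)
    if quota >= level_counts.min():
        raise ValueError(
            f"training quota {quota} leaves no held-out blocks for the "
            f"smallest test level ({int(level_counts.min())} blocks)")
    # truncate variables if cases could not support them
    n_train_min = quota * levels.size  # blocks; phrases >= blocks
    if X.shape[1] >= n_train_min:
        keep = max(1, n_train_min - 1)
        warnings.warn(f"truncating {X.shape[1]} variables to the leading "
                      f"{keep} to keep more cases than variables")
        X = X[:, :keep]
    rng = np.random.default_rng(cfg.seed)
    labels = block_label[phrase_block]
    obs_tr, obs_te, per_level = _averaged_rates(
        X, labels, phrase_block, block_label, quota, cfg.n_selections, rng,
        collect_levels=True)
    n_sel_null = cfg.n_selections_null or cfg.n_selections
    exceed_tr = exceed_te = 0
    for _ in range(cfg.n_permutations):
        perm_label = rng.permutation(block_label)
        tr, te, _ = _averaged_rates(X, perm_label[phrase_block], phrase_block,
                                    perm_label, quota, n_sel_null, rng)
        exceed_tr += tr >= obs_tr - 1e-9
        exceed_te += te >= obs_te - 1e-9
    denom = cfg.n_permutations + 1
    return PDFAResult(
        training_rate=obs_tr, training_p=(exceed_tr + 1) / denom,
        testing_rate=obs_te, testing_p=(exceed_te + 1) / denom,
        chance_rate=100.0 / levels.size, n_levels=int(levels.size),
        n_blocks=int(block_label.size), n_phrases=int(X.shape[0]),
        config=cfg, per_level_testing=per_level)


def pdfa_by_sex(scores, meta: pd.DataFrame, cfg: PDFAConfig,
                sex_column: str = "sex") -> dict[str, PDFAResult]:
    """Run the pDFA separately per sex; skips (with a warning) a sex with
    fewer than two test-factor levels."""
    X = scores.to_numpy(dtype=float) if hasattr(scores, "to_numpy") else \
        np.asarray(scores, dtype=float)
    if sex_column not in meta.columns:
        raise ValueError(f"no {sex_column!r} column in metadata")
    sexes = list(dict.fromkeys(meta[sex_column].astype(str)))
    if not sexes:
        raise ValueError("empty metadata")
    out: dict[str, PDFAResult] = {}
    for sex in sexes:
        sel = (meta[sex_column].astype(str) == sex).to_numpy()
        sub = meta.loc[sel]
        if sub[cfg.test_factor].nunique() < 2:
            warnings.warn(f"sex {sex!r} has fewer than 2 "
                          f"{cfg.test_factor} levels; skipped")
            continue
        out[sex] = pdfa(X[sel], sub.reset_index(drop=True), cfg)
    return out


def pdfa_group(scores, meta: pd.DataFrame, cfg: PDFAConfig | None = None,
               **overrides) -> PDFAResult:
    """Group-membership pDFA: group as test factor, individual as control."""
    base = cfg or PDFAConfig()
    base = replace(base, test_factor="group_id",
                   control_factor="individual_id", **overrides)
    try:
        return pdfa(scores, meta, base)
    except ValueError as err:
        if "single control level" in str(err):
            raise ValueError(str(err).replace("test level(s)",
                                              "group(s) with one individual")) from None
        raise
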