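"""Pairwise genetic relatedness from co-dominant marker genotypes.

Implements four moment estimators (Queller & Goodnight 1989; Li et al.
1993; Lynch & Ritland 1999; a Wang-2002-style similarity-category
estimator) and a dyadic maximum-likelihood estimator that maximises the
genotype-pair likelihood over the IBD coefficients (k0, k1, k2) on the
simplex, with r = k2 + k1/2.

Estimator selection follows a simulation harness: dyads of known
relatedness (parent-offspring, full-sibling, half-sibling, unrelated) are
built by explicit Mendelian construction from the population allele
frequencies, every registered estimator is applied, and estimators are
ranked by the pooled Pearson correlation between estimate and truth.

Moment estimates may fall outside [-1, 1]; raw values are preserved
internally and clamped only in the exported matrix.  The likelihood
estimator is confined to [0, 1] by construction of the simplex.

Notes on the Wang-style estimator: the observed genotype-pair similarity
category (identical / hom-het sharing / het-het sharing one allele / no
sharing) has expectation linear in (k2, k1) with coefficients given by the
exact conditional category probabilities under 0, 1 or 2 IBD alleles.  The
estimator here solves those moment equations by ordinary least squares
across loci with allele frequencies treated as known, which keeps it
linear in the indicators and therefore exactly unbiased; the published
variance-optimal weighting is not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import SquareMatrix, normalize01
from .pedigree import GenotypeTable, LocusSpec, MISSING_ALLELE

__all__ = [
    "MOMENT_ESTIMATORS",
    "ALL_ESTIMATORS",
    "RELATEDNESS_CATEGORIES",
    "RelatednessMatrix",
    "DyadSet",
    "DyadSimReport",
    "allele_frequencies",
    "moment_estimators",
    "dyadic_ml",
    "relatedness_matrix",
    "relatedness_to_distance",
    "simulate_dyads",
    "estimate_dyad_set",
    "compare_estimators",
]

MOMENT_ESTIMATORS = ("queller_goodnight", "li", "lynch_ritland", "wang")
ALL_ESTIMATORS = MOMENT_ESTIMATORS + ("dyadic_ml",)

#: true r per simulated dyad category
RELATEDNESS_CATEGORIES = {
    "parent_offspring": 0.5,
    "full_sib": 0.5,
    "half_sib": 0.25,
    "unrelated": 0.0,
}


# ---------------------------------------------------------------------------
# Allele frequencies and per-locus precomputation


def allele_frequencies(gt: GenotypeTable) -> dict[str, dict[int, float]]:
    """Gene-count allele frequencies per locus (missing alleles excluded)."""
    out: dict[str, dict[int, float]] = {}
    for l, locus in enumerate(gt.loci):
        alleles = gt.alleles[:, l, :].ravel()
        alleles = alleles[alleles != MISSING_ALLELE]
        if alleles.size == 0:
            raise ValueError(f"locus {locus}: no typed individuals")
        values, counts = np.unique(alleles, return_counts=True)
        total = counts.sum()
        out[locus] = {int(a): c / total for a, c in zip(values, counts)}
    return out


def freqs_from_loci(loci) -> dict[str, dict[int, float]]:
    """Frequency table from a list of :class:`LocusSpec`."""
    return {l.name: dict(zip(l.alleles, l.freqs)) for l in loci}


@dataclass(frozen=True)
class _LocusStats:
    """Frequency summaries a locus contributes to every estimator."""

    p: dict[int, float]
    a2: float
    a3: float
    a4: float
    s0: float                       # E[similarity | unrelated] = 2*a2 - a3
    cat_given_ibd: np.ndarray = field(repr=False)   # (4 categories, 3 IBD states)

    @classmethod
    def build(cls, p: dict[int, float]) -> "_LocusStats":
        pv = np.array(list(p.values()), dtype=float)
        a2, a3, a4 = (pv ** 2).sum(), (pv ** 3).sum(), (pv ** 4).sum()
        # conditional category probabilities (columns: 2, 1, 0 IBD alleles)
        c1 = [1.0, a2, 2 * a2 ** 2 - a4]
        c2 = [0.0, 2 * (a2 - a3), 4 * (a3 - a4)]
        p4_0 = float((pv ** 2 * (1 - pv) ** 2).sum())
        rest = 1.0 - pv[None, :] - pv[:, None]
        pair = 2 * np.outer(pv, pv) * rest ** 2
        p4_0 += float(np.triu(pair, k=1).sum())
        c4 = [0.0, 0.0, p4_0]
        c3 = [0.0, 1 - 3 * a2 + 2 * a3,
              1.0 - c1[2] - c2[2] - p4_0]
        A = np.array([c1, c2, c3, c4])
        return cls(p=dict(p), a2=float(a2), a3=float(a3), a4=float(a4),
                   s0=float(2 * a2 - a3), cat_given_ibd=A)


def _locus_stats(freqs: dict[str, dict[int, float]]) -> dict[str, _LocusStats]:
    return {name: _LocusStats.build(p) for name, p in freqs.items()}


def _pair_category(a: int, b: int, c: int, d: int) -> int:
    """0: identical genotypes; 1: hom–het sharing; 2: het–het sharing one;
    3: no shared allele."""
    if (a, b) == (c, d):
        return 0
    if a != c and a != d and b != c and b != d:
        return 3
    return 1 if (a == b or c == d) else 2


# ---------------------------------------------------------------------------
# Moment estimators (per dyad)


def _qg_terms(a, b, c, d, p):
    """Queller–Goodnight numerator/denominator with (a, b) as reference."""
    pa, pb = p[a], p[b]
    num = 0.5 * ((a == c) + (a == d) + (b == c) + (b == d)) - pa - pb
    den = 1.0 + (a == b) - pa - pb
    return num, den


def _lr_terms(a, b, c, d, p):
    """Lynch–Ritland numerator/denominator with (a, b) as reference."""
    pa, pb = p[a], p[b]
    num = pa * ((b == c) + (b == d)) + pb * ((a == c) + (a == d)) - 4 * pa * pb
    den = (1.0 + (a == b)) * (pa + pb) - 4 * pa * pb
    w = 2 * pa * pb      # locus weight divisor: weight = den / (2*pa*pb)
    return num / w, den / w


_LI_SCORE = {0: 1.0, 1: 0.75, 2: 0.5, 3: 0.0}


def _dyad_moment(g1: np.ndarray, g2: np.ndarray, loci, stats, estimator: str) -> float:
    """Multilocus moment estimate for one dyad; NaN if no shared typed loci."""
    typed = [l for l in range(len(loci))
             if MISSING_ALLELE not in g1[l] and MISSING_ALLELE not in g2[l]]
    if not typed:
        return np.nan
    if estimator == "queller_goodnight":
        nx = dx = ny = dy = 0.0
        for l in typed:
            st = stats[loci[l]]
            a, b = int(g1[l, 0]), int(g1[l, 1])
            c, d = int(g2[l, 0]), int(g2[l, 1])
            n1, d1 = _qg_terms(a, b, c, d, st.p)
            n2, d2 = _qg_terms(c, d, a, b, st.p)
            nx += n1; dx += d1; ny += n2; dy += d2
        parts = [n / d for n, d in ((nx, dx), (ny, dy)) if d != 0.0]
        return float(np.mean(parts)) if parts else np.nan
    if estimator == "li":
        num = den = 0.0
        for l in typed:
            st = stats[loci[l]]
            cat = _pair_category(int(g1[l, 0]), int(g1[l, 1]),
                                 int(g2[l, 0]), int(g2[l, 1]))
            num += _LI_SCORE[cat] - st.s0
            den += 1.0 - st.s0
        return num / den if den != 0.0 else np.nan
    if estimator == "lynch_ritland":
        nx = dx = ny = dy = 0.0
        for l in typed:
            st = stats[loci[l]]
            a, b = int(g1[l, 0]), int(g1[l, 1])
            c, d = int(g2[l, 0]), int(g2[l, 1])
            n1, d1 = _lr_terms(a, b, c, d, st.p)
            n2, d2 = _lr_terms(c, d, a, b, st.p)
            nx += n1; dx += d1; ny += n2; dy += d2
        parts = [n / d for n, d in ((nx, dx), (ny, dy)) if d != 0.0]
        return float(np.mean(parts)) if parts else np.nan
    if estimator == "wang":
        rows_X, rows_y = [], []
        for l in typed:
            A = stats[loci[l]].cat_given_ibd
            cat = _pair_category(int(g1[l, 0]), int(g1[l, 1]),
                                 int(g2[l, 0]), int(g2[l, 1]))
            y = np.zeros(4)
            y[cat] = 1.0
            # E[y] = A0 + (A2 - A0) k2 + (A1 - A0) k1  with k0 substituted out
            rows_X.append(np.column_stack([A[:, 0] - A[:, 2], A[:, 1] - A[:, 2]]))
            rows_y.append(y - A[:, 2])
        X = np.vstack(rows_X)
        yv = np.concatenate(rows_y)
        k, *_ = np.linalg.lstsq(X, yv, rcond=None)
        return float(k[0] + 0.5 * k[1])
    raise ValueError(f"unknown moment estimator {estimator!r} "
                     f"(choose from {MOMENT_ESTIMATORS})")


# ---------------------------------------------------------------------------
# Dyadic maximum likelihood


def _ibd_grid(resolution: float) -> np.ndarray:
    """(k2, k1, k0) points of the simplex at the given step size."""
    if not 0.0 < resolution <= 1.0:
        raise ValueError(f"grid resolution must lie in (0, 1], got {resolution}")
    n = int(round(1.0 / resolution))
    pts = []
    for i in range(n + 1):
        for j in range(n + 1 - i):
            pts.append((i / n, j / n, (n - i - j) / n))
    return np.array(pts)


def _ml_components(g1, g2, loci, stats, typed) -> np.ndarray:
    """(n_typed_loci, 3) conditional pair-genotype likelihoods per IBD state.

    Column order (k2, k1, k0): P(g2 | g1, #IBD alleles).  The factor P(g1)
    is common to all states and drops out of the maximisation.
    """
    C = np.empty((len(typed), 3))
    for row, l in enumerate(typed):
        p = stats[loci[l]].p
        a, b = int(g1[l, 0]), int(g1[l, 1])
        c, d = int(g2[l, 0]), int(g2[l, 1])
        hwe = p[c] ** 2 if c == d else 2 * p[c] * p[d]
        ident = 1.0 if (a, b) == (c, d) else 0.0

        def given_shared(s: int) -> float:
            if c == d:
                return p[c] if s == c else 0.0
            return (p[d] if s == c else 0.0) + (p[c] if s == d else 0.0)

        one = 0.5 * (given_shared(a) + given_shared(b))
        C[row] = (ident, one, hwe)
    return C


def _dyad_ml(g1, g2, loci, stats, grid) -> float:
    typed = [l for l in range(len(loci))
             if MISSING_ALLELE not in g1[l] and MISSING_ALLELE not in g2[l]]
    if not typed:
        return np.nan
    C = _ml_components(g1, g2, loci, stats, typed)
    lik = grid @ C.T                      # (grid points, loci)
    with np.errstate(divide="ignore"):
        loglik = np.log(lik).sum(axis=1)
    best = int(np.argmax(loglik))
    k2, k1, _ = grid[best]
    return float(k2 + 0.5 * k1)


# ---------------------------------------------------------------------------
# Matrices over a genotype table


@dataclass(frozen=True)
class RelatednessMatrix:
    """Pairwise r-hat over a set of individuals.

    ``matrix`` holds values clamped to [-1, 1]; ``raw`` preserves the
    unclamped estimates (moment estimators can overshoot).  Dyads with no
    shared typed locus are NaN in ``raw`` and listed in ``missing_dyads``.
    """

    matrix: SquareMatrix
    raw: np.ndarray = field(repr=False)
    estimator: str = ""
    freqs: dict = field(default_factory=dict, repr=False)
    missing_dyads: tuple = ()


def _pairwise(gt: GenotypeTable, freqs, fn) -> tuple[np.ndarray, list]:
    n = len(gt.individuals)
    out = np.zeros((n, n))
    missing = []
    for i in range(n):
        for j in range(i + 1, n):
            r = fn(gt.alleles[i], gt.alleles[j])
            if np.isnan(r):
                missing.append((gt.individuals[i], gt.individuals[j]))
            out[i, j] = out[j, i] = r
    return out, missing


def _finish(gt, raw, missing, estimator, freqs) -> RelatednessMatrix:
    clamped = np.clip(np.nan_to_num(raw, nan=0.0), -1.0, 1.0)
    m = SquareMatrix(gt.individuals, clamped, diagonal=0.0)
    return RelatednessMatrix(matrix=m, raw=raw, estimator=estimator,
                             freqs=freqs, missing_dyads=tuple(missing))


def moment_estimators(gt: GenotypeTable, freqs=None,
                      estimator: str = "queller_goodnight") -> RelatednessMatrix:
    """All-pairs relatedness matrix under one of the moment estimators."""
    if estimator not in MOMENT_ESTIMATORS:
        raise ValueError(f"unknown moment estimator {estimator!r}")
    freqs = freqs or allele_frequencies(gt)
    stats = _locus_stats(freqs)
    fn = lambda g1, g2: _dyad_moment(g1, g2, gt.loci, stats, estimator)
    raw, missing = _pairwise(gt, freqs, fn)
    return _finish(gt, raw, missing, estimator, freqs)


def dyadic_ml(gt: GenotypeTable, freqs=None,
              grid_resolution: float = 0.01) -> RelatednessMatrix:
    """All-pairs relatedness by dyadic maximum likelihood (simplex grid)."""
    freqs = freqs or allele_frequencies(gt)
    stats = _locus_stats(freqs)
    grid = _ibd_grid(grid_resolution)
    fn = lambda g1, g2: _dyad_ml(g1, g2, gt.loci, stats, grid)
    raw, missing = _pairwise(gt, freqs, fn)
    return _finish(gt, raw, missing, "dyadic_ml", freqs)


def relatedness_matrix(gt: GenotypeTable, freqs=None, estimator: str = "dyadic_ml",
                       grid_resolution: float = 0.01) -> RelatednessMatrix:
    if estimator == "dyadic_ml":
        return dyadic_ml(gt, freqs, grid_resolution)
    return moment_estimators(gt, freqs, estimator)


def relatedness_to_distance(rm: RelatednessMatrix) -> SquareMatrix:
    """Genetic distance for the matrix correlation stage: 1 - normalized r.

    Orients the genetic matrix the same way as the acoustic dissimilarity
    matrix, so a positive matrix correlation means "more related, more
    acoustically similar".
    """
    norm = normalize01(rm.matrix)
    v = 1.0 - norm.values
    np.fill_diagonal(v, 0.0)
    return norm.with_values(v)


# ---------------------------------------------------------------------------
# Known-relatedness dyad simulation and estimator comparison


@dataclass(frozen=True)
class DyadSet:
    """n simulated dyads of one known category."""

    g1: np.ndarray                 # (n, L, 2)
    g2: np.ndarray
    loci: tuple[str, ...]
    freqs: dict
    category: str
    true_r: float

    @property
    def n(self) -> int:
        return self.g1.shape[0]


def _hwe_draw(loci, n, rng) -> np.ndarray:
    out = np.empty((n, len(loci), 2), dtype=int)
    for l, locus in enumerate(loci):
        out[:, l, :] = rng.choice(locus.alleles, size=(n, 2), p=locus.freqs)
    return out


def _offspring(p1: np.ndarray, p2: np.ndarray, rng) -> np.ndarray:
    n, L, _ = p1.shape
    pick1 = rng.integers(0, 2, size=(n, L, 1))
    pick2 = rng.integers(0, 2, size=(n, L, 1))
    a1 = np.take_along_axis(p1, pick1, axis=2)
    a2 = np.take_along_axis(p2, pick2, axis=2)
    return np.concatenate([a1, a2], axis=2)


def simulate_dyads(loci, category: str, n: int = 100, seed=None) -> DyadSet:
    """Mendelian construction of n dyads of a known relatedness category.

    Parents are drawn from the locus allele frequencies under
    Hardy–Weinberg and offspring receive one allele from each parent; no
    IBD-coefficient shortcuts are taken.
    """
    if category not in RELATEDNESS_CATEGORIES:
        raise ValueError(f"unknown category {category!r} "
                         f"(choose from {sorted(RELATEDNESS_CATEGORIES)})")
    loci = tuple(loci)
    rng = np.random.default_rng(seed)
    if category == "unrelated":
        g1, g2 = _hwe_draw(loci, n, rng), _hwe_draw(loci, n, rng)
    elif category == "parent_offspring":
        parent = _hwe_draw(loci, n, rng)
        mate = _hwe_draw(loci, n, rng)
        g1, g2 = parent, _offspring(parent, mate, rng)
    elif category == "full_sib":
        pa, ma = _hwe_draw(loci, n, rng), _hwe_draw(loci, n, rng)
        g1, g2 = _offspring(pa, ma, rng), _offspring(pa, ma, rng)
    else:  # half_sib: one shared parent
        shared = _hwe_draw(loci, n, rng)
        m1, m2 = _hwe_draw(loci, n, rng), _hwe_draw(loci, n, rng)
        g1, g2 = _offspring(shared, m1, rng), _offspring(shared, m2, rng)
    return DyadSet(np.sort(g1, axis=2), np.sort(g2, axis=2),
                   tuple(l.name for l in loci), freqs_from_loci(loci),
                   category, RELATEDNESS_CATEGORIES[category])


def estimate_dyad_set(dyads: DyadSet, estimator: str,
                      grid_resolution: float = 0.01) -> np.ndarray:
    """r-hat for each dyad in a :class:`DyadSet` under one estimator."""
    stats = _locus_stats(dyads.freqs)
    if estimator == "dyadic_ml":
        grid = _ibd_grid(grid_resolution)
        fn = lambda g1, g2: _dyad_ml(g1, g2, dyads.loci, stats, grid)
    elif estimator in MOMENT_ESTIMATORS:
        fn = lambda g1, g2: _dyad_moment(g1, g2, dyads.loci, stats, estimator)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return np.array([fn(dyads.g1[i], dyads.g2[i]) for i in range(dyads.n)])


@dataclass(frozen=True)
class DyadSimReport:
    """Estimator comparison over simulated known-relatedness dyads."""

    summary: pd.DataFrame       # estimator x category: mean, sd
    correlations: pd.Series     # pooled Pearson r(estimate, truth) per estimator
    ranking: tuple[str, ...]    # best first; degenerate estimators last
    degenerate: tuple[str, ...] # estimators with undefined correlation
    n_per_category: int = 0

    @property
    def best(self) -> str:
        return self.ranking[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = self.summary.copy()
        df["pooled_correlation"] = [
            self.correlations.get(e, np.nan) for e in df.index.get_level_values(0)]
        return df


def compare_estimators(loci, n_per_category: int = 100, seed=None,
                       estimators=ALL_ESTIMATORS,
                       grid_resolution: float = 0.01,
                       extra_estimators=None) -> DyadSimReport:
    """Rank estimators by pooled correlation with the true r.

    Simulates ``n_per_category`` dyads for each of the four categories,
    applies every registered estimator, and ranks by the Pearson
    correlation between estimate and truth pooled over categories.
    Estimators with undefined correlation (constant output) are flagged
    and ranked last.  ``extra_estimators`` maps extra names to callables
    ``DyadSet -> array of r-hat`` so ad-hoc estimators can join the
    comparison.  Deterministic under a fixed seed.
    """
    extra = dict(extra_estimators or {})
    estimators = tuple(estimators) + tuple(extra)
    if len(estimators) < 2:
        raise ValueError("need at least two estimators to compare")
    root = np.random.SeedSequence(seed)
    cat_seeds = dict(zip(sorted(RELATEDNESS_CATEGORIES),
                         root.spawn(len(RELATEDNESS_CATEGORIES))))
    sets = {cat: simulate_dyads(loci, cat, n_per_category,
                                np.random.default_rng(cat_seeds[cat]))
            for cat in RELATEDNESS_CATEGORIES}
    truth = np.concatenate([np.full(s.n, s.true_r) for s in sets.values()])
    rows, corrs, degenerate = [], {}, []
    for est in estimators:
        if est in extra:
            est_r = {cat: np.asarray(extra[est](s), dtype=float)
                     for cat, s in sets.items()}
        else:
            est_r = {cat: estimate_dyad_set(s, est, grid_resolution)
                     for cat, s in sets.items()}
        pooled = np.concatenate([est_r[cat] for cat in sets])
        ok = ~np.isnan(pooled)
        if ok.sum() >= 2 and np.std(pooled[ok]) > 0:
            corrs[est] = float(np.corrcoef(pooled[ok], truth[ok])[0, 1])
        else:
            corrs[est] = np.nan
            degenerate.append(est)
        for cat, r in est_r.items():
            rows.append((est, cat, float(np.nanmean(r)), float(np.nanstd(r))))
    summary = pd.DataFrame(rows, columns=["estimator", "category", "mean", "sd"])
    summary = summary.set_index(["estimator", "category"])
    corr_s = pd.Series(corrs, name="pooled_correlation")
    ranked = sorted(estimators,
                    key=lambda e: (np.isnan(corrs[e]), -np.nan_to_num(corrs[e], nan=-2)))
    return DyadSimReport(summary=summary, correlations=corr_s,
                         ranking=tuple(ranked), degenerate=tuple(degenerate),
                         n_per_category=n_per_category)
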