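"""Matrix permutation tests.

Three variants:

* :func:`mantel_test` — the standard Mantel test: Pearson correlation of
  the off-diagonal entries of two labeled symmetric matrices, null built
  by simultaneously permuting rows and columns of one matrix.  One-tailed
  (greater) by default, "plus-one" p-value convention
  ``p = (exceedances + 1) / (n_permutations + 1)``; switches to exhaustive
  enumeration of all n! label permutations when ``n_perm`` covers them,
  in which case the reported p is the exact permutation p.
* :func:`mantel_exact` — full enumeration, for small n (an oracle).
* :func:`kin_category_mantel` — correlation between acoustic similarity
  and a binary kin design over parent × offspring dyads of fixed roles
  (e.g. fathers × sons); the null permutes offspring identities among the
  offspring while the parent set stays fixed, asking whether an offspring
  resembles its own parent more than other parents' offspring do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations as _all_perms

import numpy as np

from .matrix import SquareMatrix, normalize01
from .pedigree import FEMALE, MALE, Pedigree

__all__ = [
    "MantelResult",
    "CategoryDesign",
    "mantel_test",
    "mantel_exact",
    "kin_category_mantel",
    "parent_offspring_design",
]

_TAILS = ("greater", "less", "two-sided")
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class MantelResult:
    n: int
    r: float
    p: float
    n_permutations: int
    tail: str
    exact: bool = False
    method: str = "mantel"


def _check_pair(a: SquareMatrix, b: SquareMatrix) -> None:
    if a.labels != b.labels:
        raise ValueError("matrices must share identical label order")
    if a.n < 4:
        raise ValueError(f"need n >= 4, got n = {a.n}")


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    den = math.sqrt(float(xc @ xc) * float(yc @ yc))
    return float(xc @ yc / den)


def _exceeds(stat: float, observed: float, tail: str) -> bool:
    if tail == "greater":
        return stat >= observed - _TIE_EPS
    if tail == "less":
        return stat <= observed + _TIE_EPS
    return abs(stat) >= abs(observed) - _TIE_EPS


def _offdiag_checked(m: SquareMatrix, what: str) -> np.ndarray:
    v = m.offdiag()
    if np.ptp(v) == 0:
        raise ValueError(f"zero variance in the off-diagonal of the {what} matrix")
    return v


def mantel_test(a: SquareMatrix, b: SquareMatrix, n_perm: int = 9999,
                tail: str = "greater", seed=None) -> MantelResult:
    """Mantel test between two labeled symmetric matrices.

    Permutes rows and columns of ``b`` jointly.  If ``n_perm >= n! - 1``
    (and n <= 8) the test enumerates all distinct permutations instead of
    sampling, and the plus-one p equals the exact enumeration p.
    """
    _check_pair(a, b)
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    x = _offdiag_checked(a, "first")
    _offdiag_checked(b, "second")
    iu = np.triu_indices(a.n, k=1)
    bv = b.values
    observed = _corr(x, bv[iu])
    n_all = math.factorial(a.n) if a.n <= 8 else None
    if n_all is not None and n_perm >= n_all - 1:
        exceed = 0
        for perm in _all_perms(range(a.n)):
            pv = bv[np.ix_(perm, perm)][iu]
            if _exceeds(_corr(x, pv), observed, tail):
                exceed += 1
        # identity permutation is included in the enumeration, so this is
        # both the exact p and the plus-one p at n_perm = n! - 1
        return MantelResult(a.n, observed, exceed / n_all, n_all - 1, tail,
                            exact=True)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(a.n)
        pv = bv[np.ix_(perm, perm)][iu]
        if _exceeds(_corr(x, pv), observed, tail):
            exceed += 1
    return MantelResult(a.n, observed, (exceed + 1) / (n_perm + 1), n_perm, tail)


def mantel_exact(a: SquareMatrix, b: SquareMatrix, tail: str = "greater",
                 max_n: int = 7) -> MantelResult:
    """Exact Mantel p by full enumeration of all n! label permutations."""
    _check_pair(a, b)
    if a.n > max_n:
        raise ValueError(f"n = {a.n} exceeds max_n = {max_n} for enumeration")
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")
    x = _offdiag_checked(a, "first")
    _offdiag_checked(b, "second")
    iu = np.triu_indices(a.n, k=1)
    bv = b.values
    observed = _corr(x, bv[iu])
    n_all = math.factorial(a.n)
    exceed = sum(
        _exceeds(_corr(x, bv[np.ix_(perm, perm)][iu]), observed, tail)
        for perm in _all_perms(range(a.n))
    )
    return MantelResult(a.n, observed, exceed / n_all, n_all, tail,
                        exact=True, method="mantel_exact")


# ---------------------------------------------------------------------------
# Kin-category variant


@dataclass(frozen=True)
class CategoryDesign:
    """Binary parent × offspring design for one kin category.

    ``matrix[i, j] = 1`` iff parent i is the true parent of offspring j;
    0 marks a (same-role) unrelated adult–offspring dyad.  ``mask`` flags
    the cells that enter the statistic (all by default).  Every offspring
    column has exactly one 1 on unmasked cells.
    """

    parents: tuple[str, ...]
    offspring: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)
    mask: np.ndarray | None = field(default=None, repr=False)
    parent_role: str = "father"
    offspring_role: str = "son"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.parents), len(self.offspring)):
            raise ValueError("design matrix shape does not match labels")
        mask = (np.ones(m.shape, dtype=bool) if self.mask is None
                else np.asarray(self.mask, dtype=bool))
        if mask.shape != m.shape:
            raise ValueError("mask shape does not match design matrix")
        if not np.isin(m[mask], (0.0, 1.0)).all():
            raise ValueError("design values must be binary on unmasked cells")
        ones = (m * mask).sum(axis=0)
        if not np.all(ones == 1.0):
            bad = [self.offspring[j] for j in np.where(ones != 1.0)[0]]
            raise ValueError(
                f"each offspring needs exactly one true parent; bad: {bad}")
        m.flags.writeable = False
        mask.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "mask", mask)


def parent_offspring_design(pedigree: Pedigree, parent_sex: str,
                            offspring_sex: str, present=None) -> CategoryDesign:
    """Build the binary design for one role pairing from a pedigree.

    Parents are the reproductive individuals of ``parent_sex``; offspring
    the offspring-role individuals of ``offspring_sex``.  ``present``
    optionally restricts to individuals available in the acoustic matrix;
    offspring whose true parent is absent are dropped.
    """
    present = None if present is None else {str(x) for x in present}

    def ok(ind_id: str) -> bool:
        return present is None or ind_id in present

    parents = [i.id for i in pedigree.founders()
               if i.sex == parent_sex and ok(i.id)]
    parent_of = {}
    for off in pedigree.offspring():
        if off.sex != offspring_sex or not ok(off.id):
            continue
        p = off.father if parent_sex == MALE else off.mother
        if p in parents:
            parent_of[off.id] = p
    offspring = list(parent_of)
    m = np.zeros((len(parents), len(offspring)))
    for j, off in enumerate(offspring):
        m[parents.index(parent_of[off]), j] = 1.0
    roles = {MALE: ("father", "son"), FEMALE: ("mother", "daughter")}
    return CategoryDesign(tuple(parents), tuple(offspring), m,
                          parent_role=roles[parent_sex][0],
                          offspring_role=roles[offspring_sex][1])


def kin_category_mantel(acoustic: SquareMatrix, design: CategoryDesign,
                        n_perm: int = 9999, seed=None,
                        is_similarity: bool = False) -> MantelResult:
    """Matrix correlation between acoustic similarity and a kin design.

    ``acoustic`` is an individual-level dissimilarity matrix (converted to
    similarity as ``1 - normalized dissimilarity``) unless
    ``is_similarity=True``.  The statistic is the Pearson correlation over
    the unmasked parent × offspring cells; the null permutes offspring
    identities.  One-tailed for greater similarity of true pairs.
    """
    if len(design.parents) < 2 or len(design.offspring) < 2:
        raise ValueError("need >= 2 parents and >= 2 offspring "
                         "(no permutation space otherwise)")
    missing = [l for l in design.parents + design.offspring
               if l not in acoustic.labels]
    if missing:
        raise ValueError(f"design individuals missing from the acoustic "
                         f"matrix: {', '.join(missing)}")
    if is_similarity:
        sim = acoustic
    else:
        sim = normalize01(acoustic)
        v = 1.0 - sim.values
        np.fill_diagonal(v, 0.0)
        sim = sim.with_values(v)
    pi = [sim.index_of(p) for p in design.parents]
    oi = [sim.index_of(o) for o in design.offspring]
    S = sim.values[np.ix_(pi, oi)]
    mask = design.mask
    y = design.matrix[mask]
    if np.ptp(y) == 0:
        raise ValueError("design has no contrast on unmasked cells")
    x = S[mask]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the acoustic cells")
    observed = _corr(x, y)
    rng = np.random.default_rng(seed)
    n_off = len(design.offspring)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n_off)
        xs = S[:, perm][mask]
        if np.ptp(xs) == 0:
            stat = 0.0
        else:
            stat = _corr(xs, y)
        if _exceeds(stat, observed, "greater"):
            exceed += 1
    return MantelResult(n_off, observed, (exceed + 1) / (n_perm + 1),
                        n_perm, "greater", method="kin_category_mantel")
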