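"""Pedigrees, microsatellite locus panels and Mendelian genotype simulation.

The study system is a population of family groups, each consisting of a
reproductive pair (a male and an unrelated female) plus their offspring.
This module generates such pedigrees, either at random or as the fixed
seven-group composition used throughout the package as the default study
population, and drops co-dominant microsatellite genotypes through them
under Hardy–Weinberg founders and Mendelian transmission (no mutation,
no genotyping error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "LocusSpec",
    "GenotypeTable",
    "simulate_pedigree",
    "study_pedigree",
    "default_loci",
    "simulate_genotypes",
]

MALE = "M"
FEMALE = "F"
ROLE_REPRODUCTIVE = "reproductive"
ROLE_OFFSPRING = "offspring"

MISSING_ALLELE = 0  # CSV convention for an untyped allele


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str                      # "M" or "F"
    group: str
    father: str | None = None     # None = founder
    mother: str | None = None
    role: str = ROLE_REPRODUCTIVE

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass(frozen=True)
class Pedigree:
    """An ordered collection of individuals; parents precede offspring."""

    individuals: tuple[Individual, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "individuals", tuple(self.individuals))
        self.validate()

    def validate(self) -> None:
        seen: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.sex not in (MALE, FEMALE):
                raise ValueError(f"{ind.id}: sex must be 'M' or 'F', got {ind.sex!r}")
            if ind.id in seen:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            if (ind.father is None) != (ind.mother is None):
                raise ValueError(f"{ind.id}: either both parents or neither")
            for parent_id, want_sex, which in (
                (ind.father, MALE, "father"),
                (ind.mother, FEMALE, "mother"),
            ):
                if parent_id is None:
                    continue
                parent = seen.get(parent_id)
                if parent is None:
                    raise ValueError(
                        f"{ind.id}: {which} {parent_id!r} not defined before offspring"
                    )
                if parent.sex != want_sex:
                    raise ValueError(f"{ind.id}: {which} {parent_id!r} is not {want_sex}")
            seen[ind.id] = ind

    # -- queries -----------------------------------------------------------
    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(ind.id for ind in self.individuals)

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    @property
    def groups(self) -> tuple[str, ...]:
        out: list[str] = []
        for ind in self.individuals:
            if ind.group not in out:
                out.append(ind.group)
        return tuple(out)

    def members(self, group: str) -> tuple[Individual, ...]:
        return tuple(ind for ind in self.individuals if ind.group == group)

    def founders(self) -> tuple[Individual, ...]:
        return tuple(ind for ind in self.individuals if ind.is_founder)

    def offspring(self) -> tuple[Individual, ...]:
        return tuple(ind for ind in self.individuals if not ind.is_founder)

    def sex_table(self) -> dict[str, str]:
        return {ind.id: ind.sex for ind in self.individuals}

    # -- IO ----------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": [i.id for i in self.individuals],
                "sex": [i.sex for i in self.individuals],
                "group_id": [i.group for i in self.individuals],
                "father_id": [i.father or "" for i in self.individuals],
                "mother_id": [i.mother or "" for i in self.individuals],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        df = pd.read_csv(path, dtype=str).fillna("")
        inds = []
        for row in df.itertuples(index=False):
            father = row.father_id or None
            mother = row.mother_id or None
            role = ROLE_REPRODUCTIVE if father is None else ROLE_OFFSPRING
            inds.append(
                Individual(row.individual_id, row.sex, row.group_id,
                           father, mother, role)
            )
        return cls(tuple(inds))


def simulate_pedigree(
    n_groups: int,
    offspring_range: tuple[int, int] = (0, 2),
    seed: int | np.random.Generator | None = None,
    p_male_offspring: float = 0.5,
) -> Pedigree:
    """Simulate a population of family groups.

    Each group gets a reproductive male, an unrelated reproductive female,
    and a uniform random number of offspring in ``offspring_range`` with
    both parents in-group.  Deterministic under a fixed ``seed``.
    """
    if n_groups < 1:
        raise ValueError(f"n_groups must be >= 1, got {n_groups}")
    lo, hi = offspring_range
    if not (0 <= lo <= hi):
        raise ValueError(f"invalid offspring_range {offspring_range}")
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    for g in range(1, n_groups + 1):
        group = f"G{g}"
        sire, dam = f"{group}_M", f"{group}_F"
        inds.append(Individual(sire, MALE, group))
        inds.append(Individual(dam, FEMALE, group))
        n_off = int(rng.integers(lo, hi + 1))
        for k in range(1, n_off + 1):
            sex = MALE if rng.random() < p_male_offspring else FEMALE
            inds.append(
                Individual(f"{group}_O{k}", sex, group, father=sire,
                           mother=dam, role=ROLE_OFFSPRING)
            )
    return Pedigree(tuple(inds))


# Realized composition of the seven-group study population: per-group
# offspring counts and sexes (5 sons, 4 daughters across 9 offspring).
_STUDY_GROUPS: tuple[tuple[str, ...], ...] = (
    ("F", "F"),   # group 1: two daughters
    ("F",),       # group 2: one daughter
    ("M", "F"),   # group 3: son + daughter
    ("M",),       # group 4: one son
    (),           # group 5: pair only
    ("M", "M"),   # group 6: two sons
    ("M",),       # group 7: one son
)


def study_pedigree() -> Pedigree:
    """The default seven-group study population.

    Fixed composition (no randomness): 7 reproductive pairs with 0–2
    offspring each, 9 offspring in total of which 5 are sons and 4 are
    daughters.  This mirrors the field population the synthetic data
    emulate and is the pedigree used by the pipeline's simulation mode.
    """
    inds: list[Individual] = []
    for g, sexes in enumerate(_STUDY_GROUPS, start=1):
        group = f"G{g}"
        sire, dam = f"{group}_M", f"{group}_F"
        inds.append(Individual(sire, MALE, group))
        inds.append(Individual(dam, FEMALE, group))
        for k, sex in enumerate(sexes, start=1):
            inds.append(
                Individual(f"{group}_O{k}", sex, group, father=sire,
                           mother=dam, role=ROLE_OFFSPRING)
            )
    return Pedigree(tuple(inds))


# ---------------------------------------------------------------------------
# Locus panel


@dataclass(frozen=True)
class LocusSpec:
    """A co-dominant microsatellite locus.

    Alleles are integer fragment sizes (bp); ``freqs`` is the population
    allele-frequency vector (sums to 1).
    """

    name: str
    alleles: tuple[int, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        alleles = tuple(int(a) for a in self.alleles)
        freqs = tuple(float(f) for f in self.freqs)
        if len(alleles) < 1:
            raise ValueError(f"{self.name}: need >= 1 allele")
        if len(alleles) != len(set(alleles)):
            raise ValueError(f"{self.name}: duplicate allele sizes")
        if len(freqs) != len(alleles):
            raise ValueError(f"{self.name}: {len(freqs)} freqs for {len(alleles)} alleles")
        if any(f <= 0 or f > 1 for f in freqs):
            raise ValueError(f"{self.name}: frequencies must lie in (0, 1]")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: frequencies sum to {sum(freqs)}, not 1")
        object.__setattr__(self, "alleles", alleles)
        object.__setattr__(self, "freqs", freqs)

    @classmethod
    def uniform(cls, name: str, size_range: tuple[int, int], step: int = 2) -> "LocusSpec":
        lo, hi = size_range
        alleles = tuple(range(lo, hi + 1, step))
        n = len(alleles)
        return cls(name, alleles, tuple([1.0 / n] * n))


# Published panel of six indri microsatellite loci: names, fragment-size
# ranges (bp) and dinucleotide repeat motifs; observed allele frequencies
# were never published, so the default is uniform over the size ladder.
_PANEL: tuple[tuple[str, tuple[int, int]], ...] = (
    ("67HDZ25", (218, 253)),
    ("67HDZ62", (203, 217)),
    ("67HDZ18", (164, 190)),
    ("67HDZ55", (312, 334)),
    ("67HDZ180", (113, 135)),
    ("67HDZ39", (148, 162)),
)


def default_loci() -> tuple[LocusSpec, ...]:
    """Six-locus dinucleotide panel with uniform allele frequencies."""
    return tuple(LocusSpec.uniform(name, rng, step=2) for name, rng in _PANEL)


# ---------------------------------------------------------------------------
# Genotypes


class GenotypeTable:
    """Individuals × loci, two allele sizes per cell (0 = missing).

    Backed by an integer array of shape ``(n_individuals, n_loci, 2)``.
    """

    def __init__(self, individuals, loci, alleles: np.ndarray):
        self.individuals = tuple(str(i) for i in individuals)
        self.loci = tuple(str(l) for l in loci)
        a = np.asarray(alleles, dtype=int)
        if a.shape != (len(self.individuals), len(self.loci), 2):
            raise ValueError(
                f"allele array shape {a.shape} != "
                f"({len(self.individuals)}, {len(self.loci)}, 2)"
            )
        if len(set(self.individuals)) != len(self.individuals):
            raise ValueError("duplicate individual ids")
        a = np.sort(a, axis=2)  # canonical within-cell order
        a.flags.writeable = False
        self.alleles = a

    def __len__(self) -> int:
        return len(self.individuals)

    def row(self, ind_id: str) -> np.ndarray:
        """(n_loci, 2) allele array for one individual."""
        try:
            i = self.individuals.index(str(ind_id))
        except ValueError:
            raise KeyError(f"individual {ind_id!r} not genotyped") from None
        return self.alleles[i]

    def subset(self, individuals) -> "GenotypeTable":
        idx = [self.individuals.index(str(i)) for i in individuals]
        return GenotypeTable(tuple(individuals), self.loci, self.alleles[idx])

    # -- IO (long CSV: individual_id,locus,allele1_bp,allele2_bp) ----------
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, ind in enumerate(self.individuals):
            for l, locus in enumerate(self.loci):
                a1, a2 = self.alleles[i, l]
                rows.append((ind, locus, int(a1), int(a2)))
        return pd.DataFrame(rows, columns=["individual_id", "locus",
                                           "allele1_bp", "allele2_bp"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeTable":
        if df.empty:
            raise ValueError("empty genotype table")
        individuals = list(dict.fromkeys(df["individual_id"].astype(str)))
        loci = list(dict.fromkeys(df["locus"].astype(str)))
        arr = np.zeros((len(individuals), len(loci), 2), dtype=int)
        ind_ix = {v: i for i, v in enumerate(individuals)}
        loc_ix = {v: i for i, v in enumerate(loci)}
        for row in df.itertuples(index=False):
            arr[ind_ix[str(row.individual_id)], loc_ix[str(row.locus)]] = (
                int(row.allele1_bp), int(row.allele2_bp))
        return cls(tuple(individuals), tuple(loci), arr)

    @classmethod
    def from_csv(cls, path) -> "GenotypeTable":
        return cls.from_dataframe(pd.read_csv(path))


def simulate_genotypes(
    pedigree: Pedigree,
    loci,
    seed: int | np.random.Generator | None = None,
) -> GenotypeTable:
    """Drop genotypes through a pedigree.

    Founders draw two alleles per locus from the locus frequency vector
    (Hardy–Weinberg); each offspring receives one allele chosen uniformly
    from each parent at every locus.  No mutation, no missing data.
    """
    loci = tuple(loci)
    if not loci:
        raise ValueError("need at least one locus")
    rng = np.random.default_rng(seed)
    geno: dict[str, np.ndarray] = {}
    for ind in pedigree.individuals:
        cell = np.zeros((len(loci), 2), dtype=int)
        if ind.is_founder:
            for l, locus in enumerate(loci):
                cell[l] = rng.choice(locus.alleles, size=2, p=locus.freqs)
        else:
            pat, mat = geno[ind.father], geno[ind.mother]
            pick = rng.integers(0, 2, size=(len(loci), 2))
            for l in range(len(loci)):
                cell[l, 0] = pat[l, pick[l, 0]]
                cell[l, 1] = mat[l, pick[l, 1]]
        geno[ind.id] = cell
    arr = np.stack([geno[i] for i in pedigree.ids])
    return GenotypeTable(pedigree.ids, tuple(l.name for l in loci), arr)
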