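"""Synthetic song-phrase generator.

Phrases are rendered from a latent-trait model.  Every individual carries a
latent mean vector over the acoustic parameters that define a descending
phrase (unit durations, inter-unit intervals, per-unit start/end pitch and
Q50).  The latent mean of individual *i* is

    mu_i = baseline + sex offset + group effect + d_i

where the individual deviation ``d_i`` is drawn fresh for founders
(``d_i ~ N(0, sigma_ind^2)`` per parameter) and partially transmitted to
offspring with weight ``h``:

    d_i = h * d_parent + sqrt(1 - h^2) * N(0, sigma_ind^2)

``d_parent`` is the mid-parent deviation by default, or the same-sex parent
(father for sons, mother for daughters) under the sex-specific path model.
Each phrase realises ``mu_i`` plus within-individual residual noise and is
rendered as unit boundaries plus an f0 contour (linear descent plus a small
random wiggle), so that feature extraction recovers the latent parameter
values exactly when all noise terms are zero.

Heritability acts on the latent means, not on raw phrases: the
within-individual signature (residual SD) and the kin signal (``h``) are
separately tunable.  The group effect defaults to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, Pedigree
from .phrase import PhraseRecord, Unit

__all__ = [
    "Transmission",
    "SongEffectConfig",
    "PARAMETER_SCHEMA",
    "simulate_phrases",
    "individual_latents",
]

# Latent parameter schema: name -> (domain, baseline value).  Units share
# latents across phrase types (a DP2 uses the first two units' parameters).
PARAMETER_SCHEMA: dict[str, tuple[str, float]] = {
    # temporal (seconds)
    "dur_unit1": ("temporal", 1.00),
    "dur_unit2": ("temporal", 1.20),
    "dur_unit3": ("temporal", 1.40),
    "dur_int1": ("temporal", 0.30),
    "dur_int2": ("temporal", 0.35),
    # frequency (Hz); units descend in pitch within and across units
    "f0start_1": ("frequency", 780.0),
    "f0end_1": ("frequency", 600.0),
    "q50_1": ("frequency", 730.0),
    "f0start_2": ("frequency", 720.0),
    "f0end_2": ("frequency", 520.0),
    "q50_2": ("frequency", 660.0),
    "f0start_3": ("frequency", 650.0),
    "f0end_3": ("frequency", 460.0),
    "q50_3": ("frequency", 595.0),
}

_PARAMS = list(PARAMETER_SCHEMA)
_DOMAIN = np.array([PARAMETER_SCHEMA[p][0] for p in _PARAMS])
_BASELINE = np.array([PARAMETER_SCHEMA[p][1] for p in _PARAMS])


@dataclass(frozen=True)
class Transmission:
    """Parent -> offspring transmission of latent deviations.

    ``mode="midparent"``: every offspring inherits ``h`` times the mean of
    its two parents' deviations.  ``mode="sexpath"``: sons inherit from the
    father with weight ``h_father_son``, daughters from the mother with
    ``h_mother_daughter`` (each defaulting to ``h``).
    """

    mode: str = "midparent"
    h: float = 0.5
    h_father_son: float | None = None
    h_mother_daughter: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("midparent", "sexpath"):
            raise ValueError(f"unknown transmission mode {self.mode!r}")
        for name, value in (("h", self.h),
                            ("h_father_son", self.h_father_son),
                            ("h_mother_daughter", self.h_mother_daughter)):
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")

    def weight(self, sex: str) -> float:
        if self.mode == "midparent":
            return self.h
        if sex == MALE:
            return self.h if self.h_father_son is None else self.h_father_son
        return self.h if self.h_mother_daughter is None else self.h_mother_daughter


@dataclass(frozen=True)
class SongEffectConfig:
    """Effect structure and sampling design of the phrase generator.

    SDs are per acoustic domain (seconds for temporal, Hz for frequency);
    ``per_parameter_sd`` overrides the individual-mean SD for single
    parameters.  Every individual contributes
    ``songs_per_group * phrases_per_song`` phrases per phrase type, which
    must reach ``min_phrases`` (the downstream inclusion threshold).
    """

    individual_sd: dict = field(default_factory=lambda: {"temporal": 0.10,
                                                         "frequency": 30.0})
    residual_sd: dict = field(default_factory=lambda: {"temporal": 0.05,
                                                       "frequency": 15.0})
    group_sd: dict = field(default_factory=lambda: {"temporal": 0.0,
                                                    "frequency": 0.0})
    sex_offsets: dict = field(default_factory=lambda: {
        "temporal": {MALE: 0.08, FEMALE: 0.0},
        "frequency": {MALE: 0.0, FEMALE: 60.0},
    })
    transmission: dict = field(default_factory=lambda: {
        "temporal": Transmission(), "frequency": Transmission()})
    per_parameter_sd: dict = field(default_factory=dict)
    songs_per_group: int = 5
    phrases_per_song: int = 2
    phrase_types: tuple[str, ...] = ("DP2", "DP3")
    min_phrases: int = 4
    contour_wiggle_hz: float = 8.0
    contour_dt: float = 0.05

    def __post_init__(self) -> None:
        for which in ("individual_sd", "residual_sd", "group_sd"):
            for dom, sd in getattr(self, which).items():
                if sd < 0:
                    raise ValueError(f"{which}[{dom!r}] must be >= 0, got {sd}")
        for sd in self.per_parameter_sd.values():
            if sd < 0:
                raise ValueError("per_parameter_sd values must be >= 0")
        for t in self.transmission.values():
            if not isinstance(t, Transmission):
                raise ValueError("transmission values must be Transmission")
        if self.songs_per_group < 1 or self.phrases_per_song < 1:
            raise ValueError("songs_per_group and phrases_per_song must be >= 1")
        n = self.songs_per_group * self.phrases_per_song
        if n < self.min_phrases:
            raise ValueError(
                f"{n} phrases per individual per type is below the "
                f"min_phrases threshold of {self.min_phrases}")
        unknown = set(self.phrase_types) - {"DP2", "DP3"}
        if unknown:
            raise ValueError(f"unknown phrase types {sorted(unknown)}")

    def with_(self, **kw) -> "SongEffectConfig":
        return replace(self, **kw)

    # per-parameter SD vectors over the schema
    def _sd_vector(self, which: str) -> np.ndarray:
        table = getattr(self, which)
        sd = np.array([table[d] for d in _DOMAIN], dtype=float)
        if which == "individual_sd":
            for name, value in self.per_parameter_sd.items():
                if name not in PARAMETER_SCHEMA:
                    raise ValueError(f"unknown parameter {name!r}")
                sd[_PARAMS.index(name)] = value
        return sd


def _draw_latents(pedigree: Pedigree, cfg: SongEffectConfig,
                  rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Latent mean vector per individual, in pedigree (parents-first) order."""
    sd_ind = cfg._sd_vector("individual_sd")
    sd_grp = cfg._sd_vector("group_sd")
    h_by_sex = {
        sex: np.array([cfg.transmission[d].weight(sex) for d in _DOMAIN])
        for sex in (MALE, FEMALE)
    }
    group_eff = {g: rng.normal(0.0, 1.0, len(_PARAMS)) * sd_grp
                 for g in pedigree.groups}
    dev: dict[str, np.ndarray] = {}
    mu: dict[str, np.ndarray] = {}
    for ind in pedigree.individuals:
        noise = rng.normal(0.0, 1.0, len(_PARAMS)) * sd_ind
        if ind.is_founder:
            d = noise
        else:
            h = h_by_sex[ind.sex]
            parent = {}
            for dom in ("temporal", "frequency"):
                mode = cfg.transmission[dom].mode
                if mode == "midparent":
                    parent[dom] = 0.5 * (dev[ind.father] + dev[ind.mother])
                else:
                    src = ind.father if ind.sex == MALE else ind.mother
                    parent[dom] = dev[src]
            pvec = np.where(_DOMAIN == "temporal",
                            parent["temporal"], parent["frequency"])
            d = h * pvec + np.sqrt(1.0 - h ** 2) * noise
        dev[ind.id] = d
        offs = np.array([cfg.sex_offsets[dom][ind.sex] for dom in _DOMAIN])
        mu[ind.id] = _BASELINE + offs + group_eff[ind.group] + d
    return mu


def individual_latents(pedigree: Pedigree, cfg: SongEffectConfig | None = None,
                       seed=None) -> pd.DataFrame:
    """Latent parameter means per individual (rows) as a DataFrame.

    Uses the same random stream layout as :func:`simulate_phrases`, so with
    the same seed the latents match the ones underlying the phrases.
    """
    cfg = cfg or SongEffectConfig()
    rng = np.random.default_rng(seed)
    mu = _draw_latents(pedigree, cfg, rng)
    return pd.DataFrame.from_dict(mu, orient="index", columns=_PARAMS)


def _render_phrase(pid: str, ptype: str, ind, song: str, params: np.ndarray,
                   cfg: SongEffectConfig, rng: np.random.Generator) -> PhraseRecord:
    p = dict(zip(_PARAMS, params))
    n_units = {"DP2": 2, "DP3": 3}[ptype]
    t0 = 0.0
    units = []
    for k in range(1, n_units + 1):
        dur = max(p[f"dur_unit{k}"], 0.05)
        f0e = max(p[f"f0end_{k}"], 80.0)
        f0s = max(p[f"f0start_{k}"], f0e + 20.0)
        start, end = t0, t0 + dur
        n = max(2, int(round(dur / cfg.contour_dt)) + 1)
        t = np.linspace(start, end, n)
        f0 = f0s + (f0e - f0s) * (t - start) / dur
        if cfg.contour_wiggle_hz > 0:
            amp = cfg.contour_wiggle_hz * rng.uniform(0.5, 1.0)
            cycles = rng.uniform(1.0, 2.5)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            f0 = f0 + amp * np.sin(2 * np.pi * cycles * (t - start) / dur + phase)
        f0 = np.maximum(f0, 60.0)
        units.append(Unit(start, end, t, f0, q50=float(max(p[f"q50_{k}"], 100.0))))
        if k < n_units:
            t0 = end + max(p[f"dur_int{k}"], 0.01)
    return PhraseRecord(phrase_id=pid, phrase_type=ptype, individual=ind.id,
                        song=song, group=ind.group, sex=ind.sex,
                        units=tuple(units))


def simulate_phrases(pedigree: Pedigree, cfg: SongEffectConfig | None = None,
                     seed=None) -> list[PhraseRecord]:
    """Generate the phrase dataset for a pedigree.

    Every group holds ``songs_per_group`` chorus songs; every group member
    contributes ``phrases_per_song`` phrases of each phrase type to each
    song.  Deterministic under a fixed seed.
    """
    cfg = cfg or SongEffectConfig()
    rng = np.random.default_rng(seed)
    mu = _draw_latents(pedigree, cfg, rng)
    sd_res = cfg._sd_vector("residual_sd")
    phrases: list[PhraseRecord] = []
    for group in pedigree.groups:
        members = pedigree.members(group)
        for s in range(1, cfg.songs_per_group + 1):
            song = f"{group}_S{s}"
            for ind in members:
                for ptype in cfg.phrase_types:
                    for j in range(1, cfg.phrases_per_song + 1):
                        params = mu[ind.id] + rng.normal(0, 1, len(_PARAMS)) * sd_res
                        pid = f"{ind.id}_{song}_{ptype}_{j}"
                        phrases.append(_render_phrase(pid, ptype, ind, song,
                                                      params, cfg, rng))
    return phrases
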