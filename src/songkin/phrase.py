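"""Song phrases: containers and file formats.

A descending phrase (DP) is an ordered sequence of 2 (DP2) or 3 (DP3)
frequency-descending units.  Each unit carries its start/end times and a
sampled fundamental-frequency (f0) contour; optionally the frequency at
the upper limit of the second quartile of spectral energy (Q50) measured
for that unit.  Phrases arrive either from the synthetic generator or from
a phrase table + contour table (CSV), with Praat PitchTier files supported
as an alternative per-unit contour source.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Unit",
    "PhraseRecord",
    "PhraseValidationError",
    "write_phrases",
    "read_phrases",
    "read_pitch_tier",
    "write_pitch_tier",
]

UNITS_PER_TYPE = {"DP2": 2, "DP3": 3}


class PhraseValidationError(ValueError):
    """A phrase violates the structural invariants (names the phrase id)."""


@dataclass(frozen=True)
class Unit:
    """One vocal emission: [start, end] with an f0 contour sampled inside."""

    start: float
    end: float
    times: np.ndarray = field(repr=False)
    f0: np.ndarray = field(repr=False)
    q50: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.f0, dtype=float)
        order = np.argsort(t, kind="stable")
        t, f = t[order], f[order]
        t.flags.writeable = False
        f.flags.writeable = False
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "f0", f)

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PhraseRecord:
    phrase_id: str
    phrase_type: str            # "DP2" | "DP3"
    individual: str
    song: str
    group: str
    sex: str                    # "M" | "F"
    units: tuple[Unit, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "units", tuple(self.units))
        self.validate()

    def validate(self) -> None:
        pid = self.phrase_id
        want = UNITS_PER_TYPE.get(self.phrase_type)
        if want is None:
            raise PhraseValidationError(
                f"phrase {pid}: unknown phrase type {self.phrase_type!r}")
        if len(self.units) != want:
            raise PhraseValidationError(
                f"phrase {pid}: {self.phrase_type} must have {want} units, "
                f"got {len(self.units)}")
        prev_end = -np.inf
        for k, u in enumerate(self.units, start=1):
            if not u.end > u.start:
                raise PhraseValidationError(
                    f"phrase {pid}: unit {k} has end <= start")
            if u.start < prev_end:
                raise PhraseValidationError(
                    f"phrase {pid}: unit {k} overlaps the previous unit")
            prev_end = u.end
            if u.times.size < 2:
                raise PhraseValidationError(
                    f"phrase {pid}: unit {k} has fewer than 2 f0 samples")
            eps = 1e-9
            if u.times[0] < u.start - eps or u.times[-1] > u.end + eps:
                raise PhraseValidationError(
                    f"phrase {pid}: unit {k} has f0 samples outside [start, end]")
            if np.any(u.f0 <= 0):
                raise PhraseValidationError(
                    f"phrase {pid}: unit {k} has non-positive f0")

    @property
    def n_units(self) -> int:
        return len(self.units)

    def meta(self) -> dict:
        return {
            "phrase_id": self.phrase_id,
            "phrase_type": self.phrase_type,
            "individual_id": self.individual,
            "song_id": self.song,
            "group_id": self.group,
            "sex": self.sex,
        }


# ---------------------------------------------------------------------------
# CSV dialects
#
# phrase CSV:  phrase_id,song_id,individual_id,group_id,sex,phrase_type,
#              unit_index,unit_start_s,unit_end_s        (one row per unit)
# contour CSV: phrase_id,unit_index,time_s,f0_hz[,q50_hz] (one row per sample)


def write_phrases(phrases, phrase_path, contour_path) -> None:
    """Write phrase + contour tables (UTF-8, header row, '.' decimals)."""
    prow, crow = [], []
    for ph in phrases:
        for k, u in enumerate(ph.units, start=1):
            prow.append((ph.phrase_id, ph.song, ph.individual, ph.group,
                         ph.sex, ph.phrase_type, k, u.start, u.end))
            for t, f in zip(u.times, u.f0):
                crow.append((ph.phrase_id, k, t, f,
                             "" if u.q50 is None else u.q50))
    pd.DataFrame(prow, columns=[
        "phrase_id", "song_id", "individual_id", "group_id", "sex",
        "phrase_type", "unit_index", "unit_start_s", "unit_end_s",
    ]).to_csv(phrase_path, index=False)
    pd.DataFrame(crow, columns=[
        "phrase_id", "unit_index", "time_s", "f0_hz", "q50_hz",
    ]).to_csv(contour_path, index=False)


def read_phrases(phrase_path, contour_path) -> list[PhraseRecord]:
    """Read the phrase + contour tables back into PhraseRecords."""
    pdf = pd.read_csv(phrase_path, float_precision="round_trip")
    cdf = pd.read_csv(contour_path, float_precision="round_trip")
    contours = {
        key: g for key, g in cdf.groupby(["phrase_id", "unit_index"], sort=False)
    }
    phrases: list[PhraseRecord] = []
    for pid, g in pdf.groupby("phrase_id", sort=False):
        g = g.sort_values("unit_index")
        units = []
        for row in g.itertuples(index=False):
            try:
                c = contours[(pid, row.unit_index)]
            except KeyError:
                raise PhraseValidationError(
                    f"phrase {pid}: no contour samples for unit {row.unit_index}"
                ) from None
            q50 = None
            if "q50_hz" in c.columns:
                vals = c["q50_hz"].dropna().unique()
                if vals.size:
                    q50 = float(vals[0])
            units.append(Unit(float(row.unit_start_s), float(row.unit_end_s),
                              c["time_s"].to_numpy(float),
                              c["f0_hz"].to_numpy(float), q50=q50))
        first = g.iloc[0]
        phrases.append(PhraseRecord(
            phrase_id=str(pid), phrase_type=str(first["phrase_type"]),
            individual=str(first["individual_id"]), song=str(first["song_id"]),
            group=str(first["group_id"]), sex=str(first["sex"]),
            units=tuple(units)))
    return phrases


# ---------------------------------------------------------------------------
# Praat PitchTier (long and short text dialects)

_NUM = re.compile(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?")


def read_pitch_tier(path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a Praat PitchTier text file into (times, f0) arrays.

    Accepts both the long dialect (``points [1]: number = ... value = ...``)
    and the short dialect (bare numbers, one per line).
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    header, _, body = text.partition("PitchTier")
    if "ooTextFile" not in header or not body:
        raise ValueError(f"{path}: not a Praat PitchTier text file")
    nums = [float(x) for x in _NUM.findall(body)]
    if "=" in body:
        # long dialect: xmin, xmax, size, then (index, number, value) triples
        # where the bracketed point index appears in the text as well
        pairs = re.findall(
            r"number\s*=\s*(%s)\s*value\s*=\s*(%s)" % (_NUM.pattern, _NUM.pattern),
            body)
        pts = np.array(pairs, dtype=float)
    else:
        if len(nums) < 3:
            raise ValueError(f"{path}: truncated PitchTier")
        size = int(nums[2])
        vals = nums[3:3 + 2 * size]
        if len(vals) != 2 * size:
            raise ValueError(f"{path}: expected {size} points")
        pts = np.array(vals, dtype=float).reshape(size, 2)
    if pts.size == 0:
        return np.empty(0), np.empty(0)
    return pts[:, 0].copy(), pts[:, 1].copy()


def write_pitch_tier(path, times, f0, dialect: str = "short") -> None:
    """Write a (times, f0) contour as a Praat PitchTier text file."""
    t = np.asarray(times, float)
    f = np.asarray(f0, float)
    if t.shape != f.shape:
        raise ValueError("times and f0 must have equal length")
    xmin = float(t.min()) if t.size else 0.0
    xmax = float(t.max()) if t.size else 1.0
    lines = ['File type = "ooTextFile"', 'Object class = "PitchTier"', ""]
    if dialect == "short":
        lines += [repr(xmin), repr(xmax), str(t.size)]
        for ti, fi in zip(t, f):
            lines += [repr(float(ti)), repr(float(fi))]
    elif dialect == "long":
        lines += [f"xmin = {xmin!r}", f"xmax = {xmax!r}",
                  f"points: size = {t.size}"]
        for i, (ti, fi) in enumerate(zip(t, f), start=1):
            lines += [f"points [{i}]:", f"    number = {float(ti)!r}",
                      f"    value = {float(fi)!r}"]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")
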