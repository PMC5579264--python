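"""Acoustic parameters of descending phrases.

Two parameter sets are measured per phrase, mirroring standard bioacoustic
practice for unit-structured calls:

* temporal — per-unit duration ``Dur_unit_k``, inter-unit interval
  ``Dur_int_k`` (end of unit k to start of unit k+1), inter-onset interval
  ``IOI_k`` (onset to onset), and the total phrase duration;
* frequency — per-unit f0 mean/max/min, f0 at unit start and end, the
  percentage of the unit's duration elapsed at the pitch maximum (``ptmax``)
  and minimum (``ptmin``), and ``Q50``, the frequency at the upper limit of
  the second quartile of spectral energy.

``f0mean`` is the time-weighted (trapezoidal) mean of the contour rather
than the raw sample mean, so unevenly sampled contours are handled
consistently.  Ties in ``ptmax``/``ptmin`` resolve to the earliest sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phrase import PhraseRecord, PhraseValidationError, UNITS_PER_TYPE

__all__ = [
    "temporal_features",
    "frequency_features",
    "q50_from_spectrum",
    "feature_table",
    "META_COLUMNS",
    "temporal_feature_names",
    "frequency_feature_names",
]

META_COLUMNS = ["phrase_id", "phrase_type", "individual_id", "song_id",
                "group_id", "sex"]


def temporal_feature_names(phrase_type: str) -> list[str]:
    k = UNITS_PER_TYPE[phrase_type]
    names = [f"Dur_unit{i}" for i in range(1, k + 1)]
    names += [f"Dur_int{i}" for i in range(1, k)]
    names += [f"IOI{i}" for i in range(1, k)]
    names += ["Dur_total"]
    return names


def frequency_feature_names(phrase_type: str, with_q50: bool = True) -> list[str]:
    k = UNITS_PER_TYPE[phrase_type]
    per_unit = ["f0mean", "f0max", "f0min", "f0start", "f0end", "ptmax", "ptmin"]
    if with_q50:
        per_unit.append("Q50")
    return [f"{p}_unit{i}" for i in range(1, k + 1) for p in per_unit]


def temporal_features(phrase: PhraseRecord) -> dict[str, float]:
    """Temporal parameter set of one phrase.

    ``Dur_unit_k = end_k - start_k``; ``Dur_int_k = start_{k+1} - end_k``;
    ``IOI_k = start_{k+1} - start_k``; ``Dur_total = end_last - start_first``.
    """
    phrase.validate()
    out: dict[str, float] = {}
    units = phrase.units
    for i, u in enumerate(units, start=1):
        out[f"Dur_unit{i}"] = u.duration
    for i in range(1, len(units)):
        out[f"Dur_int{i}"] = units[i].start - units[i - 1].end
        out[f"IOI{i}"] = units[i].start - units[i - 1].start
    out["Dur_total"] = units[-1].end - units[0].start
    return out


def frequency_features(
    phrase: PhraseRecord,
    include_q50: bool | None = None,
) -> dict[str, float]:
    """Frequency parameter set of one phrase.

    Parameters
    ----------
    include_q50
        ``True`` — require a Q50 value per unit (error if absent);
        ``False`` — omit Q50; ``None`` (default) — include it when every
        unit carries one.
    """
    phrase.validate()
    if include_q50 is None:
        include_q50 = all(u.q50 is not None for u in phrase.units)
    out: dict[str, float] = {}
    for i, u in enumerate(phrase.units, start=1):
        t, f = u.times, u.f0
        span = t[-1] - t[0]
        if span > 0:
            mean = float(np.trapezoid(f, t) / span)
        else:  # all samples at one instant: fall back to the plain mean
            mean = float(f.mean())
        imax = int(np.argmax(f))  # argmax/argmin take the earliest tie
        imin = int(np.argmin(f))
        out[f"f0mean_unit{i}"] = mean
        out[f"f0max_unit{i}"] = float(f[imax])
        out[f"f0min_unit{i}"] = float(f[imin])
        out[f"f0start_unit{i}"] = float(f[0])
        out[f"f0end_unit{i}"] = float(f[-1])
        out[f"ptmax_unit{i}"] = 100.0 * (t[imax] - u.start) / u.duration
        out[f"ptmin_unit{i}"] = 100.0 * (t[imin] - u.start) / u.duration
        if include_q50:
            if u.q50 is None:
                raise PhraseValidationError(
                    f"phrase {phrase.phrase_id}: Q50 unavailable for unit {i} "
                    "(no measured value and no spectrum)")
            out[f"Q50_unit{i}"] = float(u.q50)
    return out


def q50_from_spectrum(freq_hz, energy) -> float:
    """Frequency below which half of the summed spectral energy lies.

    Bins are treated as uniform energy densities over the intervals between
    consecutive bin edges, so a flat two-bin spectrum over [0, 1000] Hz
    yields 500 Hz.  ``freq_hz`` are the upper edges of the bins (the first
    bin spans from 0).
    """
    f = np.asarray(freq_hz, dtype=float)
    e = np.asarray(energy, dtype=float)
    if f.shape != e.shape or f.ndim != 1 or f.size == 0:
        raise ValueError("freq_hz and energy must be equal-length 1-D arrays")
    if np.any(e < 0) or e.sum() <= 0:
        raise ValueError("energy must be non-negative with positive total")
    order = np.argsort(f)
    f, e = f[order], e[order]
    edges = np.concatenate([[0.0], f])
    cum = np.concatenate([[0.0], np.cumsum(e)])
    half = 0.5 * cum[-1]
    j = int(np.searchsorted(cum, half))
    # linear interpolation inside bin j (uniform density within a bin)
    lo_f, hi_f = edges[j - 1], edges[j]
    lo_c, hi_c = cum[j - 1], cum[j]
    if hi_c == lo_c:
        return float(hi_f)
    return float(lo_f + (half - lo_c) / (hi_c - lo_c) * (hi_f - lo_f))


def feature_table(phrases, kind: str, include_q50: bool | None = None) -> pd.DataFrame:
    """Phrases × parameters table for a single phrase type.

    Returns a DataFrame with the metadata columns first, then the feature
    columns of the requested ``kind`` ("temporal" or "frequency").
    """
    phrases = list(phrases)
    if not phrases:
        raise ValueError("no phrases supplied")
    types = {p.phrase_type for p in phrases}
    if len(types) > 1:
        raise ValueError(
            f"feature_table needs a single phrase type, got {sorted(types)}")
    if kind == "temporal":
        fn = temporal_features
    elif kind == "frequency":
        if include_q50 is None:
            include_q50 = all(u.q50 is not None
                              for p in phrases for u in p.units)
        def fn(p):  # noqa: E306
            return frequency_features(p, include_q50=include_q50)
    else:
        raise ValueError(f"kind must be 'temporal' or 'frequency', got {kind!r}")
    rows = [{**p.meta(), **fn(p)} for p in phrases]
    df = pd.DataFrame(rows)
    feat_cols = [c for c in df.columns if c not in META_COLUMNS]
    return df[META_COLUMNS + feat_cols]
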