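"""Atmospheric Δ¹⁴C bomb-pulse record: representation, interpolation, inversion.

Atmospheric ¹⁴C roughly doubled during above-ground nuclear weapons testing
(1955–1963) and has relaxed back toward the pre-bomb level since.  Because DNA
incorporates carbon at the atmospheric concentration prevailing when it is
synthesized, this transient acts as a date stamp for genomic DNA.

Conventions
-----------
* Δ¹⁴C is in per mille (‰) relative to the oxalic-acid standard and is assumed
  decay-corrected, as AMS labs report it; the corresponding *fraction value*
  is ``F = 1 + Δ¹⁴C / 1000``.
* Time is a decimal calendar year (1963.5 ≈ early July 1963).  Calendar dates
  are converted with :func:`decimal_year` via day-of-year / 365.25.
* Interpolation is linear between tabulated points and never extrapolates:
  bomb-pulse extrapolation is scientifically unsafe, so callers must supply a
  curve covering every subject's lifespan.
"""

from __future__ import annotations

import datetime as _dt
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AtmosphericCurve",
    "C14Value",
    "CurveParseError",
    "CurveRangeError",
    "decimal_year",
    "load_curve",
    "stylized_bomb_curve",
    "f_at",
    "invert_curve",
    "delta_to_f",
    "f_to_delta",
]


class CurveParseError(ValueError):
    """A curve table could not be parsed into a valid record."""


class CurveRangeError(ValueError):
    """A time point fell outside the tabulated curve range."""


def delta_to_f(delta14c):
    """Convert Δ¹⁴C (‰) to the fraction value F = 1 + Δ/1000."""
    return 1.0 + np.asarray(delta14c, dtype=float) / 1000.0


def f_to_delta(f):
    """Convert a fraction value F back to Δ¹⁴C in ‰."""
    return (np.asarray(f, dtype=float) - 1.0) * 1000.0


def decimal_year(date: "_dt.date | _dt.datetime | str") -> float:
    """Convert a calendar date (or ISO string) to a decimal year.

    Uses day-of-year / 365.25 so that all dates live on the same axis as the
    atmospheric record.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(date, _dt.datetime):
        date = date.date()
    doy = date.timetuple().tm_yday
    return date.year + (doy - 1) / 365.25


@dataclass(frozen=True)
class C14Value:
    """A genomic Δ¹⁴C measurement with its AMS accuracy.

    Parameters
    ----------
    delta14c:
        Decay-corrected Δ¹⁴C in ‰.
    sigma2_rel:
        Relative measurement accuracy at 2σ (dimensionless); AMS labs quote
        1%–3% (2σ), so values must lie in (0, 0.1].
    """

    delta14c: float
    sigma2_rel: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma2_rel <= 0.1):
            raise ValueError(
                f"sigma2_rel must be in (0, 0.1], got {self.sigma2_rel}"
            )

    @property
    def f(self) -> float:
        """Fraction value F = 1 + Δ¹⁴C/1000."""
        return float(delta_to_f(self.delta14c))


@dataclass(frozen=True)
class AtmosphericCurve:
    """Time-indexed atmospheric Δ¹⁴C record.

    ``years`` must be strictly increasing with at least two points, and the
    fraction value ``1 + Δ/1000`` must be positive everywhere.  Use
    :meth:`require_coverage` to assert that the record spans a given window
    (the analysis pipeline requires at least [1930, 2020]).
    """

    years: np.ndarray
    delta14c: np.ndarray
    source_label: str = ""

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        delta = np.asarray(self.delta14c, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "delta14c", delta)
        if years.ndim != 1 or delta.shape != years.shape:
            raise ValueError("years and delta14c must be matching 1-D arrays")
        if years.size < 2:
            raise ValueError("curve needs at least 2 tabulated points")
        if not np.all(np.diff(years) > 0):
            raise ValueError("years must be strictly increasing (no duplicates)")
        if not np.all(delta_to_f(delta) > 0):
            raise ValueError("fraction value 1 + Δ/1000 must be positive")

    @property
    def f_values(self) -> np.ndarray:
        """Tabulated fraction values F = 1 + Δ/1000."""
        return delta_to_f(self.delta14c)

    @property
    def t_min(self) -> float:
        return float(self.years[0])

    @property
    def t_max(self) -> float:
        return float(self.years[-1])

    def require_coverage(self, t_lo: float = 1930.0, t_hi: float = 2020.0) -> "AtmosphericCurve":
        """Raise :class:`CurveRangeError` unless the record spans [t_lo, t_hi]."""
        if self.t_min > t_lo or self.t_max < t_hi:
            raise CurveRangeError(
                f"curve covers [{self.t_min}, {self.t_max}], "
                f"required at least [{t_lo}, {t_hi}]"
            )
        return self


def load_curve(source, source_label: str | None = None) -> AtmosphericCurve:
    """Load an atmospheric curve from a two-column year/Δ¹⁴C table.

    Accepts a CSV path or file object (header ``year,delta14c``; ``#``
    comment lines ignored), a DataFrame, or an iterable of (year, Δ¹⁴C)
    pairs.  Rows are sorted by year; duplicate years are rejected; malformed
    rows raise :class:`CurveParseError` naming the offending line.
    """
    label = source_label
    if isinstance(source, pd.DataFrame):
        df = source.iloc[:, :2].copy()
        df.columns = ["year", "delta14c"]
    elif isinstance(source, (str, Path)) or hasattr(source, "read"):
        if isinstance(source, (str, Path)):
            label = label or str(source)
        try:
            df = pd.read_csv(source, comment="#")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise CurveParseError(f"could not read curve table: {exc}") from exc
        if df.shape[1] < 2:
            raise CurveParseError("curve table needs two columns (year, delta14c)")
        df = df.iloc[:, :2]
        df.columns = ["year", "delta14c"]
    else:
        rows = list(source)
        if not rows:
            raise CurveParseError("empty curve table")
        df = pd.DataFrame(rows, columns=["year", "delta14c"])

    if df.empty:
        raise CurveParseError("empty curve table")

    years = pd.to_numeric(df["year"], errors="coerce")
    delta = pd.to_numeric(df["delta14c"], errors="coerce")
    bad = years.isna() | delta.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise CurveParseError(f"malformed curve row at data line {line}: "
                              f"{df.iloc[line - 1].tolist()}")

    order = np.argsort(years.to_numpy(), kind="stable")
    y = years.to_numpy(dtype=float)[order]
    d = delta.to_numpy(dtype=float)[order]
    dup = np.flatnonzero(np.diff(y) == 0)
    if dup.size:
        raise CurveParseError(f"duplicate year in curve table: {y[dup[0]]}")
    return AtmosphericCurve(y, d, source_label=label or "loaded")


def stylized_bomb_curve(
    pre_bomb: float = -5.0,
    peak_year: float = 1963.5,
    peak: float = 970.0,
    efolding_years: float = 16.0,
    t_start: float = 1900.0,
    t_end: float = 2030.0,
    step: float = 0.25,
) -> AtmosphericCurve:
    """Deterministic stylized bomb-pulse curve for analyses without a data file.

    Flat at ``pre_bomb`` ‰ before 1955, linear rise from 1955 to ``peak_year``
    reaching ``peak`` ‰, then exponential relaxation back toward the pre-bomb
    level with e-folding time ``efolding_years``.  Tabulated at ``step`` ≤ 0.25
    years, with knots forced at the 1955 onset and at the peak.  The shape
    mimics the northern-hemisphere atmospheric record closely enough to
    exercise every pipeline stage; it is a stylized stand-in, not a
    calibration dataset.
    """
    if peak_year <= 1955.0:
        raise ValueError("peak year must be after the 1955 rise onset")
    if efolding_years <= 0:
        raise ValueError("e-folding time must be positive")
    if not (0 < step <= 0.25):
        raise ValueError("tabulation step must be in (0, 0.25]")
    if t_start >= 1955.0 or t_end <= peak_year:
        raise ValueError("tabulation range must bracket the bomb pulse")

    grid = np.arange(t_start, t_end + 0.5 * step, step)
    grid = np.unique(np.concatenate([grid, [1955.0, peak_year, t_end]]))
    grid = grid[(grid >= t_start) & (grid <= t_end)]

    delta = np.empty_like(grid)
    rise = (grid >= 1955.0) & (grid <= peak_year)
    fall = grid > peak_year
    delta[grid < 1955.0] = pre_bomb
    delta[rise] = pre_bomb + (peak - pre_bomb) * (grid[rise] - 1955.0) / (
        peak_year - 1955.0
    )
    delta[fall] = pre_bomb + (peak - pre_bomb) * np.exp(
        -(grid[fall] - peak_year) / efolding_years
    )
    curve = AtmosphericCurve(grid, delta, source_label="stylized bomb pulse")
    return curve.require_coverage(max(1930.0, t_start), min(2020.0, t_end))


def f_at(curve: AtmosphericCurve, t) -> "float | np.ndarray":
    """Fraction value F(t) by linear interpolation; no extrapolation.

    Raises :class:`CurveRangeError` if any ``t`` lies outside the tabulated
    range.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < curve.t_min) or np.any(t_arr > curve.t_max):
        raise CurveRangeError(
            f"time {t} outside curve range [{curve.t_min}, {curve.t_max}]"
        )
    out = np.interp(t_arr, curve.years, curve.f_values)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def invert_curve(
    curve: AtmosphericCurve,
    f_target: float,
    window: Sequence[float],
) -> list[float]:
    """All years in ``window`` where the interpolated curve crosses ``f_target``.

    Each crossing is located by linear interpolation within its bracketing
    tabulated segment.  Returns an ascending (possibly empty) list.  Knot
    values exactly equal to the target count as one crossing.
    """
    t_lo, t_hi = float(window[0]), float(window[1])
    if t_lo >= t_hi:
        raise ValueError(f"window must satisfy t_lo < t_hi, got [{t_lo}, {t_hi}]")
    if t_lo < curve.t_min or t_hi > curve.t_max:
        raise CurveRangeError(
            f"window [{t_lo}, {t_hi}] outside curve range "
            f"[{curve.t_min}, {curve.t_max}]"
        )

    inner = curve.years[(curve.years > t_lo) & (curve.years < t_hi)]
    knots = np.concatenate([[t_lo], inner, [t_hi]])
    fvals = np.interp(knots, curve.years, curve.f_values)
    resid = fvals - f_target

    crossings: list[float] = []
    for i in range(knots.size - 1):
        r0, r1 = resid[i], resid[i + 1]
        if r0 == 0.0:
            crossings.append(float(knots[i]))
        elif r0 * r1 < 0.0:
            t_cross = knots[i] + (knots[i + 1] - knots[i]) * r0 / (r0 - r1)
            crossings.append(float(t_cross))
    if resid[-1] == 0.0:
        crossings.append(float(knots[-1]))

    # collapse duplicates from coincident knot hits
    out: list[float] = []
    for t in sorted(crossings):
        if not out or t - out[-1] > 1e-12:
            out.append(t)
    return out
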