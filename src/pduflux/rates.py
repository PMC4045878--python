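"""Volumetric and specific rate equations for batch and fed-batch operation.

Two operating modes are covered:

* **batch** (constant volume): volumetric rates from concentration
  differences, ``Q = (P_final − P_initial)/Δt`` in g/L.h, and specific
  rates ``q = Q·1000/X`` in mg/g_CDW.h with ``X`` the cell density
  (g_CDW/L).
* **variable-volume fed-batch**: absolute rates from mass (V·C) balances,
  ``production = (P_f·V_f − P_i·V_i)/Δt`` and
  ``consumption = (S_f·V_f − S_feed·V_feed − S_i·V_i)/Δt`` in g/h, and
  specific rates ``q = rate·1000/x`` with ``x`` the total biocatalyst
  (g_CDW).

Consumption rates are returned negative (table convention); helpers expose
magnitudes.  The default estimator uses only the two window-endpoint
samples, mirroring the difference equations; a least-squares slope over all
samples in the window is available as ``estimator="regression"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network import MOLAR_MASS, UnknownSpeciesError

__all__ = [
    "SPECIES_COLUMNS",
    "TimeSeries",
    "Window",
    "FeedStep",
    "RateResult",
    "batch_volumetric_rate",
    "batch_specific_rate",
    "fedbatch_production_rate",
    "fedbatch_consumption_rate",
    "fedbatch_specific_rate",
    "specific_rate",
    "cumulative_molar_yield",
    "product_molar_ratio",
]

#: Species id -> CSV column name (the on-disk dialect).
SPECIES_COLUMNS: dict[str, str] = {
    "glycerol": "glycerol_g_L",
    "3hpa": "hpa_g_L",
    "3hp": "hp_g_L",
    "13pdo": "pdo_g_L",
    "carbohydrazide": "scavenger_g_L",
    "3hpa_complex": "hpa_complex_g_L",
}

_REQUIRED_COLUMNS = ("time_h", "volume_L", "glycerol_g_L", "hpa_g_L", "hp_g_L", "pdo_g_L")


@dataclass
class TimeSeries:
    """Sampled reactor state: time (h), volume (L) and concentrations (g/L).

    ``biomass`` is the cell density X (g_CDW/L) in batch mode and the total
    biocatalyst amount x (g_CDW) in fed-batch mode (resting cells: constant).
    """

    data: pd.DataFrame
    mode: str = "fedbatch"
    biomass: float = 6.0

    def __post_init__(self) -> None:
        if self.mode not in ("batch", "fedbatch"):
            raise ValueError(f"mode must be 'batch' or 'fedbatch', got {self.mode!r}")
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"time series missing columns: {missing}")
        t = self.data["time_h"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing")
        if np.any(self.data["volume_L"].to_numpy(float) <= 0):
            raise ValueError("volume_L must be positive")
        conc_cols = [c for c in self.data.columns if c.endswith("_g_L")]
        if np.any(self.data[conc_cols].to_numpy(float) < -1e-12):
            raise ValueError("concentrations must be non-negative")
        if self.mode == "batch":
            v = self.data["volume_L"].to_numpy(float)
            if len(v) and not np.allclose(v, v[0], rtol=1e-9, atol=1e-12):
                raise ValueError("batch mode requires constant volume")

    # -- accessors ---------------------------------------------------------

    @property
    def times(self) -> np.ndarray:
        return self.data["time_h"].to_numpy(float)

    def column(self, species: str) -> str:
        try:
            col = SPECIES_COLUMNS[species]
        except KeyError:
            raise UnknownSpeciesError(f"unknown species id {species!r}") from None
        if col not in self.data.columns:
            raise UnknownSpeciesError(f"species {species!r} not recorded in series")
        return col

    def snap_index(self, t: float) -> int:
        """Index of the recorded sample nearest to ``t`` (ties -> earlier)."""
        times = self.times
        if len(times) == 0:
            raise ValueError("empty time series")
        return int(np.argmin(np.abs(times - t)))

    def span(self) -> tuple[float, float]:
        times = self.times
        return float(times[0]), float(times[-1])


@dataclass(frozen=True)
class Window:
    """Analysis window [t_start, t_end] in hours."""

    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end must exceed t_start: {self}")


@dataclass(frozen=True)
class FeedStep:
    """One constant-rate feeding step of a variable-volume protocol."""

    t_start: float
    t_end: float
    feed_conc_g_L: float
    feed_rate_L_h: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end must exceed t_start: {self}")
        if self.feed_rate_L_h < 0 or self.feed_conc_g_L < 0:
            raise ValueError("feed rate and concentration must be >= 0")

    @property
    def mass_rate_g_h(self) -> float:
        """Substrate mass feed rate F = S_feed · F_vol, g/h."""
        return self.feed_conc_g_L * self.feed_rate_L_h

    @property
    def duration_h(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class RateResult:
    """A single estimated rate with its window and units.

    ``stderr_mg_gCDW_h`` is the standard error of the regression slope
    (propagated to specific units) and is only available for the
    regression estimator; the endpoint estimator reports none.
    """

    species: str
    window: Window
    volumetric_g_L_h: Optional[float]  # batch only
    absolute_g_h: Optional[float]      # fed-batch only
    specific_mg_gCDW_h: float
    direction: str                     # "production" | "consumption"
    estimator: str = "endpoint"
    stderr_mg_gCDW_h: Optional[float] = None

    @property
    def magnitude_mg_gCDW_h(self) -> float:
        return abs(self.specific_mg_gCDW_h)


def _window_indices(series: TimeSeries, w: Window) -> tuple[int, int]:
    """Snap window endpoints to the nearest samples; require two distinct."""
    lo, hi = series.span()
    if w.t_end < lo or w.t_start > hi:
        raise ValueError(f"window {w} outside series span [{lo}, {hi}]")
    i0 = series.snap_index(w.t_start)
    i1 = series.snap_index(w.t_end)
    if i1 <= i0:
        raise ValueError(f"window {w} snaps to fewer than 2 samples")
    return i0, i1


def _slope(t: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y against t."""
    return float(np.polyfit(t, y, 1)[0])


def _slope_stderr(t: np.ndarray, y: np.ndarray) -> float:
    """Standard error of the least-squares slope (0 for a 2-point fit)."""
    if len(t) < 3:
        return 0.0
    return float(stats.linregress(t, y).stderr)


def batch_volumetric_rate(
    series: TimeSeries, species: str, w: Window, estimator: str = "endpoint"
) -> float:
    """Volumetric rate Q = (C_final − C_initial)/Δt in g/L.h (batch).

    Negative for consumed species.
    """
    if series.mode != "batch":
        raise ValueError("batch_volumetric_rate requires a batch-mode series")
    col = series.column(species)
    i0, i1 = _window_indices(series, w)
    t = series.times
    if estimator == "endpoint":
        c = series.data[col].to_numpy(float)
        return (c[i1] - c[i0]) / (t[i1] - t[i0])
    if estimator == "regression":
        sel = slice(i0, i1 + 1)
        return _slope(t[sel], series.data[col].to_numpy(float)[sel])
    raise ValueError(f"unknown estimator {estimator!r}")


def batch_specific_rate(Q: float, X: float) -> float:
    """Specific rate q = Q·1000/X in mg/g_CDW.h (X in g_CDW/L)."""
    if X <= 0:
        raise ValueError(f"cell density X must be > 0, got {X}")
    return Q * 1000.0 / X


def fedbatch_production_rate(
    series: TimeSeries, species: str, w: Window, estimator: str = "endpoint"
) -> float:
    """Absolute production rate (P_f·V_f − P_i·V_i)/Δt in g/h."""
    col = series.column(species)
    i0, i1 = _window_indices(series, w)
    t = series.times
    pv = series.data[col].to_numpy(float) * series.data["volume_L"].to_numpy(float)
    if estimator == "endpoint":
        return (pv[i1] - pv[i0]) / (t[i1] - t[i0])
    if estimator == "regression":
        sel = slice(i0, i1 + 1)
        return _slope(t[sel], pv[sel])
    raise ValueError(f"unknown estimator {estimator!r}")


def fedbatch_consumption_rate(
    series: TimeSeries,
    species: str,
    w: Window,
    step: FeedStep,
    estimator: str = "endpoint",
) -> float:
    """Substrate rate (S_f·V_f − S_feed·V_feed − S_i·V_i)/Δt in g/h.

    ``V_feed = F_vol·Δt`` is the feed volume added during the window, so the
    window must lie within a single constant-rate feed step; spanning a
    feed-rate change is an error (analyse per step).  Negative when the
    substrate is consumed.
    """
    col = series.column(species)
    i0, i1 = _window_indices(series, w)
    t = series.times
    tol = 1e-9
    if t[i0] < step.t_start - tol or t[i1] > step.t_end + tol:
        raise ValueError(
            f"window [{t[i0]}, {t[i1]}] spans a feed-rate change; "
            f"analyse each feed step separately (step is [{step.t_start}, {step.t_end}])"
        )
    sv = series.data[col].to_numpy(float) * series.data["volume_L"].to_numpy(float)
    if estimator == "endpoint":
        dt = t[i1] - t[i0]
        v_feed = step.feed_rate_L_h * dt
        return (sv[i1] - step.feed_conc_g_L * v_feed - sv[i0]) / dt
    if estimator == "regression":
        sel = slice(i0, i1 + 1)
        # subtract the running feed input so the residual mass is linear in t
        feed_in = step.mass_rate_g_h * (t[sel] - t[i0])
        return _slope(t[sel], sv[sel] - feed_in)
    raise ValueError(f"unknown estimator {estimator!r}")


def fedbatch_specific_rate(rate_g_h: float, x: float) -> float:
    """Specific rate q = rate·1000/x in mg/g_CDW.h (x in g_CDW)."""
    if x <= 0:
        raise ValueError(f"biocatalyst amount x must be > 0, got {x}")
    return rate_g_h * 1000.0 / x


def specific_rate(
    series: TimeSeries,
    species: str,
    w: Window,
    step: Optional[FeedStep] = None,
    estimator: str = "endpoint",
) -> RateResult:
    """Mode-dispatching specific rate with full bookkeeping.

    In batch mode the volumetric formula applies; in fed-batch mode the
    variable-volume mass balance applies, with the feed term included for
    the fed substrate when ``step`` is given.
    """
    stderr = None
    if estimator == "regression":
        i0, i1 = _window_indices(series, w)
        sel = slice(i0, i1 + 1)
        t = series.times[sel]
        col = series.column(species)
        y = series.data[col].to_numpy(float)[sel]
        if series.mode != "batch":
            y = y * series.data["volume_L"].to_numpy(float)[sel]
            if step is not None:
                y = y - step.mass_rate_g_h * (t - t[0])
        stderr = _slope_stderr(t, y) * 1000.0 / series.biomass
    if series.mode == "batch":
        Q = batch_volumetric_rate(series, species, w, estimator)
        q = batch_specific_rate(Q, series.biomass)
        return RateResult(
            species, w, Q, None, q,
            "consumption" if q < 0 else "production", estimator, stderr,
        )
    if step is not None:
        r = fedbatch_consumption_rate(series, species, w, step, estimator)
    else:
        r = fedbatch_production_rate(series, species, w, estimator)
    q = fedbatch_specific_rate(r, series.biomass)
    return RateResult(
        species, w, None, r, q,
        "consumption" if q < 0 else "production", estimator, stderr,
    )


def _feed_mass_in(schedule: Sequence[FeedStep], t0: float, t1: float) -> float:
    """Substrate mass (g) fed between t0 and t1 by a step schedule."""
    total = 0.0
    for step in schedule or ():
        overlap = min(t1, step.t_end) - max(t0, step.t_start)
        if overlap > 0:
            total += step.mass_rate_g_h * overlap
    return total


def _moles_produced(series: TimeSeries, species: str, i0: int, i1: int) -> float:
    col = series.column(species)
    v = series.data["volume_L"].to_numpy(float)
    c = series.data[col].to_numpy(float)
    return (c[i1] * v[i1] - c[i0] * v[i0]) / MOLAR_MASS[species]


def cumulative_molar_yield(
    series: TimeSeries,
    w: Window,
    schedule: Optional[Sequence[FeedStep]] = None,
    numerator: Iterable[str] = ("3hp", "13pdo"),
) -> float:
    """Moles of product(s) formed per mole of glycerol consumed over ``w``.

    Glycerol consumption accounts for feed input:
    ``consumed = S_i·V_i + feed_in − S_f·V_f`` (all converted to moles).
    Pass ``numerator=("3hp", "13pdo", "3hpa", "3hpa_complex")`` to audit C3
    conservation (the result is then 1 up to solver error on noiseless
    simulated data).
    """
    i0, i1 = _window_indices(series, w)
    t = series.times
    consumed = -_moles_produced(series, "glycerol", i0, i1) + _feed_mass_in(
        schedule, t[i0], t[i1]
    ) / MOLAR_MASS["glycerol"]
    if consumed <= 0:
        raise ValueError("no glycerol consumed over the window")
    produced = 0.0
    for sp in numerator:
        if sp in ("3hpa_complex", "carbohydrazide") and SPECIES_COLUMNS[sp] not in series.data.columns:
            continue
        produced += _moles_produced(series, sp, i0, i1)
    return produced / consumed


def product_molar_ratio(series: TimeSeries, w: Window) -> float:
    """Molar ratio of 3HP to 1,3PDO produced over the window."""
    i0, i1 = _window_indices(series, w)
    pdo = _moles_produced(series, "13pdo", i0, i1)
    if pdo <= 0:
        raise ValueError("no 1,3PDO produced over the window; ratio undefined")
    return _moles_produced(series, "3hp", i0, i1) / pdo
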