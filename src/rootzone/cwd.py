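"""Cumulative water deficit: daily running sum of ET minus liquid infiltration.

The cumulative water deficit (CWD) tracks the water drawn from below-ground
storage: a running sum of (ET - P_in) that initiates on the first day of net
water loss and terminates once rain (plus snow melt) has returned the sum to
zero.  Each initiation-to-termination span is a CWD *event*.  Accumulations
that never return to zero within five years ("runaway" deficits, indicating
lateral water inputs or data bias) are flagged and excluded from all
downstream statistics.  A snow accumulation/melt model converts snowfall
into delayed liquid input, and an energy-to-mass helper converts latent-heat
fluxes (W m-2) into ET mass units (mm/day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365
RUNAWAY_YEARS = 5

SECONDS_PER_DAY = 86400.0


@dataclass
class SnowState:
    """Degree-day snow model state and parameters.

    Melt occurs above ``melt_threshold`` (default 1 degC) at
    ``melt_rate`` mm per day per degree above the threshold, capped by the
    available snow water equivalent.
    """

    snowpack: float = 0.0
    melt_threshold: float = 1.0
    melt_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.snowpack < 0:
            raise ValueError("snowpack must be non-negative")
        if not self.melt_rate > 0:
            raise ValueError("melt_rate must be positive")


@dataclass(frozen=True)
class CwdEvent:
    """One deficit event: a contiguous span of positive CWD.

    ``start_day`` inclusive, ``end_day`` exclusive, 0-based.  Events longer
    than five years are flagged ``discarded_runaway`` and ignored downstream.
    """

    event_id: int
    start_day: int
    end_day: int
    max_cwd: float
    day_of_max: int
    discarded_runaway: bool = False

    @property
    def length(self) -> int:
        return self.end_day - self.start_day


@dataclass
class CwdSeries:
    """Daily CWD values with event labels and exclusion flags.

    ``event_id`` is -1 outside events.  ``masked`` marks days excluded from
    the sensitivity analysis (post-rewetting); ``discarded`` marks days of
    runaway events excluded from *all* statistics.  CWD values themselves
    are never altered by masking.
    """

    day_index: np.ndarray
    cwd: np.ndarray
    event_id: np.ndarray
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]
    discarded: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.cwd)
        if self.masked is None:
            self.masked = np.zeros(n, dtype=bool)
        if self.discarded is None:
            self.discarded = np.zeros(n, dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day_index": self.day_index,
                "cwd": self.cwd,
                "event_id": self.event_id,
                "masked": self.masked,
                "discarded": self.discarded,
            }
        )


def snow_water_balance(
    rain: Sequence[float],
    snowfall: Sequence[float],
    temp: Sequence[float],
    state: SnowState | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the degree-day snow mass balance.

    Daily melt is ``melt_rate * max(0, temp - melt_threshold)``, capped by
    the snow available (carried pack plus same-day snowfall).  Liquid input
    to the soil is ``P_in = rain + melt``.

    Returns ``(p_in, snowpack)`` where ``snowpack`` holds the end-of-day
    snow water equivalent.  Conservation holds exactly:
    sum(snowfall) = delta(snowpack) + sum(melt).
    """
    if state is None:
        state = SnowState()
    rain = np.asarray(rain, dtype=float)
    snowfall = np.asarray(snowfall, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if not (len(rain) == len(snowfall) == len(temp)):
        raise ValueError("rain, snowfall and temp must have equal length")
    if np.any(rain < 0) or np.any(snowfall < 0):
        raise ValueError("precipitation cannot be negative")

    n = len(rain)
    p_in = np.empty(n)
    pack_series = np.empty(n)
    pack = state.snowpack
    for i in range(n):
        available = pack + snowfall[i]
        potential = state.melt_rate * max(0.0, temp[i] - state.melt_threshold)
        melt = min(available, potential)
        pack = available - melt
        p_in[i] = rain[i] + melt
        pack_series[i] = pack
    state.snowpack = pack
    return p_in, pack_series


def _latent_heat_linear(temp, pressure=None):
    """Latent heat of vaporization (J/kg), linear in temperature.

    lambda(T) = (2.501 - 0.002361 T) e6, the standard approximation over
    the meteorological range; the (weak) air-pressure dependence is left to
    user-supplied functions.
    """
    return (2.501 - 0.002361 * np.asarray(temp, dtype=float)) * 1.0e6


def latent_heat_to_mass(
    le_flux,
    temp=20.0,
    pressure: float = 101325.0,
    latent_heat_fn: Callable[[np.ndarray, float], np.ndarray] | None = None,
) -> np.ndarray:
    """Convert a latent-heat flux (W m-2) to ET in mass units (mm/day).

    ``et = le_flux * 86400 / lambda(temp, pressure)`` with lambda in J/kg;
    1 kg m-2 of water equals 1 mm.  The latent-heat function is pluggable;
    the default is linear in temperature and ignores pressure.
    """
    le_flux = np.asarray(le_flux, dtype=float)
    if not np.all(np.isfinite(le_flux)):
        raise ValueError("le_flux must be finite")
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    fn = latent_heat_fn or _latent_heat_linear
    lam = np.asarray(fn(temp, pressure), dtype=float)
    return le_flux * SECONDS_PER_DAY / lam


def compute_cwd(
    et: Sequence[float],
    p_in: Sequence[float],
    runaway_days: int = RUNAWAY_YEARS * DAYS_PER_YEAR,
) -> tuple[CwdSeries, list[CwdEvent]]:
    """Compute the daily CWD series and its events.

    A new event starts on the first day with a positive daily deficit
    (ET - P_in > 0) while no event is open; the running sum is floored at
    zero, at which point the event closes (the closing day belongs to the
    event).  Events spanning more than ``runaway_days`` are flagged
    ``discarded_runaway`` and their days marked ``discarded``.
    """
    et = np.asarray(et, dtype=float)
    p_in = np.asarray(p_in, dtype=float)
    if len(et) != len(p_in):
        raise ValueError("et and p_in must have equal length")
    if len(et) < 2:
        raise ValueError("series must cover at least 2 days")
    if np.any(et < 0):
        raise ValueError("et must be non-negative")

    n = len(et)
    deficit = et - p_in
    cwd = np.zeros(n)
    event_id = np.full(n, -1, dtype=int)
    events: list[CwdEvent] = []

    open_start = -1
    running = 0.0
    ev_max = 0.0
    ev_argmax = -1
    next_id = 0

    def _close(end_day: int) -> None:
        nonlocal open_start, next_id, running, ev_max, ev_argmax
        ev = CwdEvent(
            event_id=next_id,
            start_day=open_start,
            end_day=end_day,
            max_cwd=ev_max,
            day_of_max=ev_argmax,
            discarded_runaway=(end_day - open_start) > runaway_days,
        )
        events.append(ev)
        next_id += 1
        open_start = -1
        running = 0.0
        ev_max = 0.0
        ev_argmax = -1

    for i in range(n):
        if open_start < 0:
            if deficit[i] > 0.0:
                open_start = i
                running = deficit[i]
                ev_max = running
                ev_argmax = i
                cwd[i] = running
                event_id[i] = next_id
            # else: outside any event, cwd stays 0
        else:
            running += deficit[i]
            if running <= 0.0:
                running = 0.0
                cwd[i] = 0.0
                event_id[i] = next_id
                _close(i + 1)
            else:
                cwd[i] = running
                event_id[i] = next_id
                if running > ev_max:
                    ev_max = running
                    ev_argmax = i
    if open_start >= 0:
        _close(n)

    discarded = np.zeros(n, dtype=bool)
    for ev in events:
        if ev.discarded_runaway:
            discarded[ev.start_day : ev.end_day] = True

    series = CwdSeries(
        day_index=np.arange(n),
        cwd=cwd,
        event_id=event_id,
        discarded=discarded,
    )
    return series, events


def mask_post_rewetting(
    series: CwdSeries, events: list[CwdEvent], fraction: float = 0.9
) -> CwdSeries:
    """Flag event days after partial rewetting for exclusion from sensitivity fits.

    Within each event, days after the event's CWD maximum are masked from
    the moment rain has reduced the CWD below ``fraction`` times that
    maximum (and for the rest of the event).  This removes the
    relieved-stress phase in which topsoil rewetting boosts activity before
    the deficit is fully compensated; the rising limb, including transient
    dips while the deficit is still building, is retained.  CWD values are
    unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    masked = series.masked.copy()
    for ev in events:
        triggered = False
        for i in range(ev.day_of_max + 1, ev.end_day):
            if triggered or series.cwd[i] < fraction * ev.max_cwd:
                triggered = True
                masked[i] = True
    return CwdSeries(
        day_index=series.day_index,
        cwd=series.cwd,
        event_id=series.event_id,
        masked=masked,
        discarded=series.discarded,
    )


def annual_max_cwd(
    series: CwdSeries,
    year_index: Sequence[int] | None = None,
    days_per_year: int = DAYS_PER_YEAR,
) -> pd.Series:
    """Annual maximum CWD over non-discarded days.

    ``year_index`` assigns each day to a calendar year; when omitted, years
    are consecutive ``days_per_year``-day blocks.  A year whose days are all
    discarded (runaway accumulation) yields NaN.  Events spanning a year
    boundary contribute to each year the maximum of the CWD values falling
    within it.
    """
    n = len(series.cwd)
    if n == 0:
        raise ValueError("empty series")
    if year_index is None:
        if n < days_per_year:
            raise ValueError("need at least one full year of data")
        year_index = np.asarray(series.day_index) // days_per_year
    else:
        year_index = np.asarray(year_index)

    valid = ~series.discarded
    df = pd.DataFrame({"year": year_index, "cwd": np.where(valid, series.cwd, np.nan)})
    return df.groupby("year")["cwd"].max()
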