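"""Weather predictors for the yield model.

Computes the three weather exposures the yield model uses —
growing degree-days (GDD), extreme degree-days (EDD) and a seasonal
crop water deficit index (CDI) — from daily weather, and the per-crop
standardization applied to all predictors before model fitting.

Degree-days use the single-sine method: the diurnal temperature cycle is
interpolated as one sine wave between ``tmin`` and ``tmax`` and the area
between two temperature thresholds is integrated in closed form. GDD
accumulates heat between a crop's base and ceiling temperature; EDD
accumulates heat above a damage threshold with no upper cap, the standard
extreme-degree-day convention.

The deficit index used here is the normalized seasonal shortfall of
precipitation relative to potential evapotranspiration (PET),

    CDI = sum_d max(0, PET_d - P_d) / sum_d PET_d  in [0, 1].

Soil-moisture-accounting alternatives exist; the definition is isolated
behind :func:`crop_water_deficit_index` so a different construction is a
drop-in replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CropCalendar",
    "PredictorScaling",
    "DEFAULT_CALENDARS",
    "single_sine_degree_days",
    "seasonal_degree_days",
    "crop_water_deficit_index",
    "standardize_panel",
    "unstandardize_panel",
    "read_weather",
    "write_weather",
    "read_panel",
    "write_panel",
    "load_calendars",
]

CROPS = ("barley", "corn", "cotton", "rice", "soybeans", "wheat")

PREDICTORS = ("t", "cdi", "gdd", "edd")
SCALED_PREDICTORS = ("cdi", "gdd", "edd")


@dataclass(frozen=True)
class CropCalendar:
    """Growing-season window (day-of-year) and temperature thresholds for one crop.

    The defaults shipped in :data:`DEFAULT_CALENDARS` are conventional
    values used in the degree-day literature, not fitted quantities; they
    are configuration and can be overridden via :func:`load_calendars`.
    """

    crop: str
    season_start: int
    season_end: int
    gdd_base: float
    gdd_ceiling: float
    edd_threshold: float

    def __post_init__(self) -> None:
        if not (self.season_start < self.season_end):
            raise ValueError(
                f"{self.crop}: season_start ({self.season_start}) must precede "
                f"season_end ({self.season_end})"
            )
        if not (self.gdd_base < self.gdd_ceiling <= self.edd_threshold):
            raise ValueError(
                f"{self.crop}: need gdd_base < gdd_ceiling <= edd_threshold, got "
                f"{self.gdd_base}, {self.gdd_ceiling}, {self.edd_threshold}"
            )


DEFAULT_CALENDARS: Mapping[str, CropCalendar] = {
    "barley": CropCalendar("barley", 91, 243, 0.0, 26.0, 26.0),
    "corn": CropCalendar("corn", 91, 273, 8.0, 29.0, 29.0),
    "cotton": CropCalendar("cotton", 91, 304, 12.0, 32.0, 32.0),
    "rice": CropCalendar("rice", 105, 288, 8.0, 33.0, 33.0),
    "soybeans": CropCalendar("soybeans", 121, 288, 10.0, 30.0, 30.0),
    "wheat": CropCalendar("wheat", 60, 196, 0.0, 26.0, 26.0),
}


@dataclass
class PredictorScaling:
    """Per-crop scale factors dividing each predictor (one SD per unit).

    ``sds`` maps predictor name -> the standard deviation by which the raw
    column was divided; ``base_year`` is the year at which the trend is
    centered.
    """

    crop: str
    sds: dict[str, float] = field(default_factory=dict)
    base_year: int = 0

    def __post_init__(self) -> None:
        for name, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"{self.crop}: scale for {name} must be > 0, got {sd}")


# ---------------------------------------------------------------------------
# degree-days
# ---------------------------------------------------------------------------


def _dd_above(threshold, m, a):
    """Mean of max(T - threshold, 0) over one sine period T = m + a sin."""
    threshold = np.asarray(threshold, dtype=float)
    lo = m - a  # tmin
    hi = m + a  # tmax
    out = np.zeros(np.broadcast(threshold, m, a).shape)
    below = threshold <= lo
    above = threshold >= hi
    mid = ~(below | above)
    out = np.where(below, m - threshold, out)
    if np.any(mid):
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(mid & (a > 0), (threshold - m) / np.where(a > 0, a, 1.0), 0.0)
        phi = np.arcsin(np.clip(frac, -1.0, 1.0))
        dd = ((m - threshold) * (np.pi / 2 - phi) + a * np.cos(phi)) / np.pi
        out = np.where(mid, dd, out)
    return out


def single_sine_degree_days(tmin, tmax, base, ceiling=np.inf):
    """Degree-days for one day from the single-sine diurnal interpolation.

    Integrates ``clamp(T(h) - base, 0, ceiling - base)`` over one day, where
    T(h) is the sine interpolation between ``tmin`` and ``tmax``. With
    ``ceiling=inf`` this is the uncapped accumulation above ``base`` (the
    extreme-degree-day form). The constant-temperature day ``tmax == tmin``
    is the analytic limit of the formula; no special branch is needed.

    Accepts scalars or broadcastable arrays; returns degree-days (deg C day).
    """
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in daily weather")
    base = np.asarray(base, dtype=float)
    ceiling = np.asarray(ceiling, dtype=float)
    if np.any(base >= ceiling):
        raise ValueError("need base < ceiling")
    m = (tmax + tmin) / 2.0
    a = (tmax - tmin) / 2.0
    # clamp(T-b, 0, c-b) == max(T-b, 0) - max(T-c, 0), so the capped
    # accumulation is the difference of two uncapped ones.
    result = _dd_above(base, m, a) - np.where(
        np.isinf(ceiling), 0.0, _dd_above(np.where(np.isinf(ceiling), 0.0, ceiling), m, a)
    )
    return result if result.shape else float(result)


WEATHER_COLUMNS = ("county_id", "date", "tmin", "tmax", "precip", "pet")


def _season_slice(weather: pd.DataFrame, calendar: CropCalendar) -> pd.DataFrame:
    w = weather.copy()
    dates = pd.to_datetime(w["date"])
    doy = dates.dt.dayofyear
    w = w.loc[(doy >= calendar.season_start) & (doy <= calendar.season_end)]
    if w.empty:
        raise ValueError(f"no weather rows inside {calendar.crop} season window")
    # every day of the window must be present exactly once (per year)
    got = set(pd.to_datetime(w["date"]).dt.dayofyear)
    expected = set(range(calendar.season_start, calendar.season_end + 1))
    missing = sorted(expected - got)
    if missing:
        raise ValueError(
            f"{calendar.crop}: missing {len(missing)} day(s) in season window: "
            f"{missing[:10]}{'...' if len(missing) > 10 else ''}"
        )
    return w


def seasonal_degree_days(weather: pd.DataFrame, calendar: CropCalendar) -> tuple[float, float]:
    """Seasonal (GDD, EDD) totals for one county-year of daily weather.

    ``weather`` must contain tmin/tmax columns and a date column covering
    the full season window; gaps raise with the missing days listed.
    """
    w = _season_slice(weather, calendar)
    gdd = float(
        np.sum(
            single_sine_degree_days(
                w["tmin"].to_numpy(), w["tmax"].to_numpy(), calendar.gdd_base, calendar.gdd_ceiling
            )
        )
    )
    edd = float(
        np.sum(
            single_sine_degree_days(
                w["tmin"].to_numpy(), w["tmax"].to_numpy(), calendar.edd_threshold, np.inf
            )
        )
    )
    return gdd, edd


def crop_water_deficit_index(weather: pd.DataFrame, calendar: CropCalendar) -> float:
    """Normalized seasonal water deficit: sum max(0, PET - P) / sum PET, in [0,1]."""
    w = _season_slice(weather, calendar)
    pet = w["pet"].to_numpy(dtype=float)
    precip = w["precip"].to_numpy(dtype=float)
    if np.any(pet < 0) or np.any(precip < 0):
        raise ValueError("pet and precip must be non-negative")
    total_pet = pet.sum()
    if total_pet == 0:
        warnings.warn("seasonal PET is zero; defining CDI = 0", stacklevel=2)
        return 0.0
    return float(np.maximum(pet - precip, 0.0).sum() / total_pet)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def standardize_panel(
    panel: pd.DataFrame, base_year: int | None = None
) -> tuple[pd.DataFrame, dict[str, PredictorScaling]]:
    """Divide cdi/gdd/edd by their per-crop pooled SD; center the trend.

    The SD is taken across all county-years of each crop (sample SD,
    ddof=1). The trend column ``t`` becomes ``year - base_year`` (default:
    the earliest year in the panel). Returns the standardized panel and the
    recorded scalings for inverse transforms.
    """
    if panel.empty:
        raise ValueError("empty panel")
    out = panel.copy()
    if base_year is None:
        base_year = int(out["year"].min())
    out["t"] = out["year"].astype(float) - base_year
    scalings: dict[str, PredictorScaling] = {}
    for crop, grp in out.groupby("crop", sort=True):
        sds = {}
        for name in SCALED_PREDICTORS:
            sd = float(grp[name].std(ddof=1))
            if not np.isfinite(sd) or sd <= 0:
                raise ValueError(f"zero-variance predictor '{name}' for crop '{crop}'")
            sds[name] = sd
            out.loc[grp.index, name] = grp[name] / sd
        scalings[crop] = PredictorScaling(crop=str(crop), sds=sds, base_year=base_year)
    return out, scalings


def unstandardize_panel(panel: pd.DataFrame, scalings: Mapping[str, PredictorScaling]) -> pd.DataFrame:
    """Inverse of :func:`standardize_panel` (restores raw predictor scales)."""
    out = panel.copy()
    for crop, grp in out.groupby("crop", sort=True):
        sc = scalings[str(crop)]
        for name in SCALED_PREDICTORS:
            out.loc[grp.index, name] = grp[name] * sc.sds[name]
        out.loc[grp.index, "year"] = grp["t"] + sc.base_year
    return out


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(WEATHER_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weather table missing columns: {sorted(missing)}")
    return df


def write_weather(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# daily weather: tmin/tmax degC, precip/pet mm/day, date ISO-8601\n")
        df.to_csv(fh, index=False)


PANEL_COLUMNS = ("county_id", "year", "crop", "log_yield", "t", "cdi", "gdd", "edd")


def read_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = set(PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    return df


def write_panel(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# yield panel: log_yield in log(yield units/acre); t in years from base;"
                 " cdi/gdd/edd standardized per crop when produced by standardize_panel\n")
        df.to_csv(fh, index=False)


def load_calendars(path) -> dict[str, CropCalendar]:
    """Read crop calendars from a YAML file keyed by crop name."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        crop: CropCalendar(
            crop=crop,
            season_start=int(v["season_start"]),
            season_end=int(v["season_end"]),
            gdd_base=float(v["gdd_base"]),
            gdd_ceiling=float(v["gdd_ceiling"]),
            edd_threshold=float(v["edd_threshold"]),
        )
        for crop, v in raw.items()
    }
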