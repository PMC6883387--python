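"""Climatic covariates for vineyard water-status modelling.

Derives, from raw daily station meteorology, the covariates used by the
stem-water-potential models: the daily maximum vapour pressure deficit
(``vpd_max``, kPa, from Tmax and minimum relative humidity), FAO-56
Penman-Monteith reference evapotranspiration (``et0``, mm d⁻¹), growing
degree days accumulated from 1 April with a 0 °C base (``gdd``, °C·d), and
the ordinal day of year (``doy``).  Also provides the Pearson correlation
diagnostic across covariates on sampling days.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

__all__ = [
    "Site",
    "WeatherDay",
    "saturation_vapor_pressure",
    "vpd_max",
    "extraterrestrial_radiation",
    "reference_et0",
    "growing_degree_days",
    "derive_climate_table",
    "climate_correlation_matrix",
]

#: Solar constant, MJ m-2 min-1 (FAO-56).
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1 (FAO-56).
STEFAN_BOLTZMANN = 4.903e-9

WEATHER_COLUMNS = ["date", "tmax", "tmin", "rh_min", "rh_max", "radiation", "wind", "rain"]


@dataclass(frozen=True)
class Site:
    """Fixed station constants needed by the FAO-56 ET0 calculation.

    Parameters
    ----------
    latitude_deg : float
        Site latitude in decimal degrees (positive north).
    altitude_m : float
        Elevation above sea level in metres; sets the psychrometric constant.
    """

    latitude_deg: float
    altitude_m: float

    def __post_init__(self):
        if not (math.isfinite(self.latitude_deg) and math.isfinite(self.altitude_m)):
            raise ValueError("site latitude and altitude must be finite")
        if not -90.0 <= self.latitude_deg <= 90.0:
            raise ValueError(f"latitude {self.latitude_deg} outside [-90, 90]")


@dataclass(frozen=True)
class WeatherDay:
    """One station-day of raw meteorology.

    Units: temperatures °C, relative humidity %, global radiation MJ m⁻² d⁻¹,
    wind speed m s⁻¹ (measured at 2 m), rainfall mm.
    """

    date: _dt.date
    tmax: float
    tmin: float
    rh_min: float
    rh_max: float
    radiation: float
    wind: float
    rain: float

    def __post_init__(self):
        vals = [self.tmax, self.tmin, self.rh_min, self.rh_max, self.radiation, self.wind, self.rain]
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"non-finite weather value on {self.date}")
        if self.tmax < self.tmin:
            raise ValueError(f"tmax < tmin on {self.date}")
        if not (0.0 <= self.rh_min <= 100.0 and 0.0 <= self.rh_max <= 100.0):
            raise ValueError(f"relative humidity outside [0, 100] on {self.date}")
        if self.rh_max < self.rh_min:
            raise ValueError(f"rh_max < rh_min on {self.date}")
        if self.radiation < 0 or self.wind < 0 or self.rain < 0:
            raise ValueError(f"negative radiation/wind/rain on {self.date}")

    @property
    def doy(self) -> int:
        return self.date.timetuple().tm_yday


def saturation_vapor_pressure(t):
    """Saturation vapour pressure over water, kPa, by the Tetens formula.

    es(T) = 0.6108 · exp(17.27·T / (T + 237.3)), T in °C (FAO-56 eq. 11).
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature must be finite")
    if np.any(t <= -237.3):
        raise ValueError("temperature at or below -237.3 °C is outside the Tetens domain")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return es if es.ndim else float(es)


def vpd_max(tmax, rh_min):
    """Daily maximum vapour pressure deficit, kPa.

    Uses the day's maximum temperature and minimum relative humidity:
    VPD_max = es(Tmax) · (1 − RHmin/100).
    """
    tmax = np.asarray(tmax, dtype=float)
    rh_min = np.asarray(rh_min, dtype=float)
    if np.any(rh_min < 0) or np.any(rh_min > 100) or not np.all(np.isfinite(rh_min)):
        raise ValueError("rh_min must lie in [0, 100]")
    out = saturation_vapor_pressure(tmax) * (1.0 - rh_min / 100.0)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def extraterrestrial_radiation(doy, latitude_deg):
    """Daily extraterrestrial radiation Ra, MJ m⁻² d⁻¹ (FAO-56 eq. 21)."""
    doy = np.asarray(doy, dtype=float)
    phi = math.radians(latitude_deg)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * np.sin(delta) + math.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    ra = np.asarray(ra)
    return ra if ra.ndim else float(ra)


def reference_et0(day: WeatherDay, site: Site) -> float:
    """FAO-56 Penman-Monteith reference (grass) evapotranspiration, mm d⁻¹.

    Daily formulation with handbook defaults: soil heat flux G = 0, albedo
    0.23, actual vapour pressure from (es(Tmin)·RHmax + es(Tmax)·RHmin)/200,
    clear-sky radiation (0.75 + 2e-5·z)·Ra, wind speed taken as measured at
    2 m.  Tiny negative results are truncated to 0.
    """
    if day.radiation is None or day.wind is None or not (
        math.isfinite(day.radiation) and math.isfinite(day.wind)
    ):
        raise ValueError("radiation and wind are required for ET0 (no silent default)")
    tmean = 0.5 * (day.tmax + day.tmin)
    es_tmax = saturation_vapor_pressure(day.tmax)
    es_tmin = saturation_vapor_pressure(day.tmin)
    es = 0.5 * (es_tmax + es_tmin)
    ea = (es_tmin * day.rh_max + es_tmax * day.rh_min) / 200.0
    # slope of the saturation curve at Tmean (FAO-56 eq. 13)
    delta = 4098.0 * saturation_vapor_pressure(tmean) / (tmean + 237.3) ** 2
    pressure = 101.3 * ((293.0 - 0.0065 * site.altitude_m) / 293.0) ** 5.26
    gamma = 0.000665 * pressure
    # net radiation: shortwave less longwave (FAO-56 eqs. 38-40)
    rns = (1.0 - 0.23) * day.radiation
    ra = extraterrestrial_radiation(day.doy, site.latitude_deg)
    rso = (0.75 + 2e-5 * site.altitude_m) * ra
    # relative shortwave bounded to [1/3, 1]: the lower bound is the
    # zero-sunshine Angstrom limit (0.25·Ra over 0.75·Ra), the upper the
    # clear-sky cap the FAO-56 daily formulation prescribes
    rel_rs = 1.0 if rso <= 0 else min(max(day.radiation / rso, 1.0 / 3.0), 1.0)
    tmax_k4 = (day.tmax + 273.16) ** 4
    tmin_k4 = (day.tmin + 273.16) ** 4
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * math.sqrt(max(ea, 0.0)))
        * (1.35 * rel_rs - 0.35)
    )
    rn = rns - rnl
    num = 0.408 * delta * rn + gamma * (900.0 / (tmean + 273.0)) * day.wind * (es - ea)
    et0 = num / (delta + gamma * (1.0 + 0.34 * day.wind))
    return max(float(et0), 0.0)


def _as_weather_frame(weather) -> pd.DataFrame:
    if isinstance(weather, pd.DataFrame):
        missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
        if missing:
            raise ValueError(f"weather table missing columns: {missing}")
        return weather
    rows = [dataclasses.asdict(d) if isinstance(d, WeatherDay) else d for d in weather]
    return pd.DataFrame(rows)


def growing_degree_days(weather, season_start: tuple[int, int] = (4, 1), base: float = 0.0) -> pd.Series:
    """Cumulative growing degree days per day, °C·d.

    Daily increment max(0, (Tmax+Tmin)/2 − base), summed from ``season_start``
    (month, day; default 1 April, around budbreak).  The input series must be
    daily and contiguous; a gap raises an error listing the missing days.
    """
    df = _as_weather_frame(weather)
    dates = pd.to_datetime(df["date"])
    expected = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
    if len(expected) != len(dates) or not (pd.DatetimeIndex(dates) == expected).all():
        missing = expected.difference(pd.DatetimeIndex(dates))
        days = [str(d) for d in missing.date]
        raise ValueError(f"weather series has date gaps; missing days: {days}")
    start = pd.Timestamp(year=dates.iloc[0].year, month=season_start[0], day=season_start[1])
    if dates.iloc[0] > start:
        raise ValueError(
            f"series starts {dates.iloc[0].date()}, after the GDD season start {start.date()}"
        )
    tmean = 0.5 * (df["tmax"].to_numpy(float) + df["tmin"].to_numpy(float))
    inc = np.maximum(tmean - base, 0.0)
    inc[dates.to_numpy() < start.to_numpy()] = 0.0
    return pd.Series(np.cumsum(inc), index=df.index, name="gdd")


def derive_climate_table(weather, site: Site) -> pd.DataFrame:
    """Per-day derived covariates: doy, vpd_max, et0, cumulative gdd.

    One output row per input day; tmax and radiation are carried through for
    the correlation diagnostics.  Per-day failures are re-raised with the
    offending row index.
    """
    df = _as_weather_frame(weather).reset_index(drop=True)
    gdd = growing_degree_days(df)
    rows = []
    for i, rec in df.iterrows():
        try:
            day = WeatherDay(
                date=pd.Timestamp(rec["date"]).date(),
                tmax=float(rec["tmax"]), tmin=float(rec["tmin"]),
                rh_min=float(rec["rh_min"]), rh_max=float(rec["rh_max"]),
                radiation=float(rec["radiation"]), wind=float(rec["wind"]),
                rain=float(rec["rain"]),
            )
            rows.append({
                "date": day.date,
                "doy": day.doy,
                "tmax": day.tmax,
                "vpd_max": vpd_max(day.tmax, day.rh_min),
                "et0": reference_et0(day, site),
                "gdd": float(gdd.iloc[i]),
                "radiation": day.radiation,
            })
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from err
    return pd.DataFrame(rows)


def climate_correlation_matrix(
    derived: pd.DataFrame,
    columns: tuple[str, ...] = ("tmax", "vpd_max", "et0", "radiation", "doy"),
    mask_ns: bool = False,
    alpha: float = 0.05,
):
    """Pearson correlation matrix of climatic covariates on sampling days.

    Returns ``(r, p)`` DataFrames (symmetric, unit diagonal).  With
    ``mask_ns=True`` entries whose two-sided p-value exceeds ``alpha`` are set
    to NaN, mirroring the customary "ns" presentation.  Zero-variance columns
    are flagged with a warning and their correlations reported as NaN.
    """
    if len(derived) < 3:
        raise ValueError("need at least 3 sampling days for a correlation matrix")
    cols = [c for c in columns if c in derived.columns]
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    x = derived[cols].to_numpy(float)
    degenerate = [cols[j] for j in range(k) if np.ptp(x[:, j]) == 0.0]
    if degenerate:
        warnings.warn(f"zero-variance columns, correlation undefined: {degenerate}")
    for i in range(k):
        for j in range(i + 1, k):
            if cols[i] in degenerate or cols[j] in degenerate:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = _stats.pearsonr(x[:, i], x[:, j])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    if mask_ns:
        rdf = rdf.mask((pdf > alpha) & ~np.eye(k, dtype=bool))
    return rdf, pdf
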