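"""Synthetic vineyard water-status studies.

Generates complete in-silico field campaigns with the statistical structure
the analysis assumes: a daily weather season (1 April – 30 September) with a
seasonal temperature cycle and AR(1) anomalies, per-plot predawn leaf water
potential trajectories that decline with accumulated demand and partially
recover after rainfall, and paired consecutive-day SWP observations drawn
from a chosen true model plus homoscedastic Gaussian noise.

Defaults emulate the Bordeaux campaigns the models were developed on:
18 plots over a season, five vines per plot, six two-day campaigns between
DOY 159 and 257, sampling-day Tmax within [23.8, 38.9] °C, PLWP within
[−0.90, −0.01] MPa, SWP noise 0.164 MPa (the published model 5 training
RMSE), and soil classes (free-draining / clayey / water-table) that spread
season-end water deficit across the observed range.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .climate import Site, derive_climate_table, vpd_max
from .forms import ModelParams, get_form, predict_swp, published_params

__all__ = [
    "SyntheticStudyConfig",
    "StudyBundle",
    "generate_weather_season",
    "generate_plwp_trajectories",
    "generate_observations",
    "generate_study",
]

SOIL_CLASSES = ("free_draining", "clayey", "water_table")
#: daily PLWP decline rate (MPa/d at full demand) and decline floor per class
_SOIL_RATE = {"free_draining": 0.0115, "clayey": 0.0055, "water_table": 0.0028}
_SOIL_FLOOR = {"free_draining": -1.5, "clayey": -0.75, "water_table": -0.30}
#: water-table plots equilibrate with a constant supply: PLWP mean-reverts
#: to this level, so late-season values stall (the paper-style matched-PLWP
#: pairing then finds within-plot pairs even without measurement noise)
_WT_EQUILIBRIUM = -0.20
_WT_RELAXATION = 0.2

_DEFAULT_CAMPAIGNS = ((159, 160), (179, 180), (199, 200), (218, 219), (238, 239), (256, 257))


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Study conditions for one synthetic campaign season."""

    n_plots: int = 18
    n_vines_per_plot: int = 5
    campaigns: tuple = _DEFAULT_CAMPAIGNS
    true_form: str = "M5"
    true_params: ModelParams | None = None
    noise_sd_swp: float = 0.164
    noise_sd_plwp: float = 0.02
    tmax_range: tuple = (23.8, 38.9)
    plwp_range: tuple = (-0.90, -0.01)
    missingness: float = 0.0
    year: int = 2018
    latitude_deg: float = 45.0
    altitude_m: float = 20.0
    campaign_tmax_day2_sd: float = 3.0
    plot_soil_profiles: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.tmax_range[0] > self.tmax_range[1] or self.plwp_range[0] > self.plwp_range[1]:
            raise ValueError("ranges must be ordered (min, max)")
        days = [d for pair in self.campaigns for d in pair]
        if days != sorted(days):
            raise ValueError("campaigns must be strictly increasing DOY pairs")
        if not 0.0 <= self.missingness < 1.0:
            raise ValueError("missingness must lie in [0, 1)")
        if self.plot_soil_profiles is not None:
            if len(self.plot_soil_profiles) != self.n_plots:
                raise ValueError("plot_soil_profiles must have one class per plot")
            bad = set(self.plot_soil_profiles) - set(SOIL_CLASSES)
            if bad:
                raise ValueError(f"unknown soil classes {bad}")

    @property
    def resolved_params(self) -> ModelParams:
        return self.true_params if self.true_params is not None else published_params(self.true_form)

    @property
    def soil_profiles(self) -> tuple:
        if self.plot_soil_profiles is not None:
            return self.plot_soil_profiles
        return tuple(SOIL_CLASSES[i % 3] for i in range(self.n_plots))

    @property
    def site(self) -> Site:
        return Site(latitude_deg=self.latitude_deg, altitude_m=self.altitude_m)


def _rng(seed):
    return np.random.default_rng(seed)


def _season_dates(year: int):
    start = _dt.date(year, 4, 1)
    end = _dt.date(year, 9, 30)
    n = (end - start).days + 1
    return [start + _dt.timedelta(days=i) for i in range(n)]


def generate_weather_season(config: SyntheticStudyConfig, seed=None) -> pd.DataFrame:
    """One daily weather season, 1 April – 30 September.

    Tmax follows a seasonal sinusoid peaking in midsummer plus an AR(1)
    anomaly; minimum relative humidity is anticorrelated with Tmax (wetter on
    rain days), which yields sampling-day VPD_max spanning roughly the
    1.2–5.6 kPa band; radiation is clear-sky extraterrestrial radiation times
    a cloudiness factor; rainfall is episodic.  On campaign days Tmax is
    redrawn inside ``config.tmax_range`` (day 2 contrasts with day 1 by a
    Gaussian step of sd ``campaign_tmax_day2_sd``), and campaign days plus
    the preceding day are kept dry so the shared-PLWP assumption holds.
    """
    rng = _rng(config.seed if seed is None else seed)
    dates = _season_dates(config.year)
    doy = np.array([d.timetuple().tm_yday for d in dates])
    n = len(dates)

    base = 15.5 + 11.5 * np.sin(np.pi * (doy - 91) / 183.0)
    anom = np.empty(n)
    anom[0] = rng.normal(0, 2.5)
    eps = rng.normal(0, 2.5, n)
    for i in range(1, n):
        anom[i] = 0.7 * anom[i - 1] + eps[i]
    tmax = base + anom

    wet = rng.random(n) < 0.25
    rain = np.where(wet, rng.gamma(1.2, 5.0, n), 0.0)

    lo, hi = config.tmax_range
    campaign_days = {d for pair in config.campaigns for d in pair}
    dry_days = campaign_days | {d - 1 for pair in config.campaigns for d in pair}
    for d1, d2 in config.campaigns:
        i1 = int(np.where(doy == d1)[0][0])
        i2 = int(np.where(doy == d2)[0][0])
        t1 = rng.uniform(lo, hi)
        t2 = float(np.clip(t1 + rng.normal(0.0, config.campaign_tmax_day2_sd), lo, hi))
        tmax[i1], tmax[i2] = t1, t2
    for i in range(n):
        if doy[i] in dry_days:
            rain[i] = 0.0
            wet[i] = False

    tmin = tmax - np.clip(rng.normal(9.0, 1.5, n), 3.0, 15.0)
    # afternoon humidity anticorrelated with heat, with enough day-to-day
    # scatter that the sampling-day Tmax-VPDmax correlation sits near the
    # 0.83 reported for the field campaigns (not the near-1 of a
    # deterministic link), while VPDmax spans roughly 1.2-5.6 kPa
    rh_min = np.clip(103.0 - 1.9 * tmax + rng.normal(0, 15.0, n) + 15.0 * wet, 16.0, 92.0)
    rh_max = np.clip(rh_min + rng.uniform(25.0, 45.0, n), None, 98.0)
    rh_max = np.maximum(rh_max, rh_min)

    from .climate import extraterrestrial_radiation

    ra = extraterrestrial_radiation(doy, config.latitude_deg)
    kt = np.clip(np.where(wet, 0.35, 0.70) + rng.normal(0, 0.06, n), 0.10, 0.78)
    radiation = ra * kt
    wind = rng.gamma(4.0, 0.5, n)

    return pd.DataFrame({
        "date": dates, "tmax": tmax, "tmin": tmin, "rh_min": rh_min,
        "rh_max": rh_max, "radiation": radiation, "wind": wind, "rain": rain,
    })


def generate_plwp_trajectories(weather: pd.DataFrame, config: SyntheticStudyConfig,
                               seed=None) -> pd.DataFrame:
    """Daily per-plot predawn leaf water potential trajectories (MPa ≤ 0).

    PLWP declines with temperature-modulated demand at a soil-class rate
    (free-draining > clayey > water-table), saturating at a class floor, and
    rainfall recharges it toward zero.  Absent rain the day-to-day change
    stays within 0.02 MPa, so the consecutive-day shared-PLWP assumption of
    the pairing design holds by construction.  Values are clipped into
    ``config.plwp_range``.
    """
    rng = _rng(config.seed + 1 if seed is None else seed)
    doys = [d for pair in config.campaigns for d in pair]
    wdoy = pd.to_datetime(weather["date"]).dt.dayofyear.to_numpy()
    if max(doys) > wdoy.max() or min(doys) < wdoy.min():
        raise ValueError("campaign days fall outside weather coverage")
    tmax = weather["tmax"].to_numpy(float)
    rain = weather["rain"].to_numpy(float)
    lo, hi = config.plwp_range
    rows = []
    for ip in range(config.n_plots):
        soil = config.soil_profiles[ip]
        scale = rng.uniform(0.75, 1.25)
        rate = _SOIL_RATE[soil] * scale
        floor = _SOIL_FLOOR[soil]
        psi = -0.03
        for i in range(len(weather)):
            demand = rate * float(np.clip((tmax[i] - 12.0) / 18.0, 0.0, 1.3))
            if soil == "water_table":
                step = _WT_RELAXATION * (_WT_EQUILIBRIUM * scale - psi) - demand
            else:
                step = -demand
            # soil water changes slowly: consecutive-day drift stays within
            # 0.02 MPa absent rain, supporting the shared-PLWP pairing design
            psi = max(psi + float(np.clip(step, -0.02, 0.02)), floor)
            if rain[i] > 1.0:
                # partial soil recharge: relax a fraction of the deficit
                psi = psi * (1.0 - min(0.007 * rain[i], 0.6))
            psi = min(psi, -0.001)
            rows.append({
                "plot": f"P{ip + 1:02d}", "soil_class": soil,
                "date": weather["date"].iloc[i], "doy": int(wdoy[i]),
                "plwp": float(np.clip(psi, lo, hi)),
            })
    return pd.DataFrame(rows)


_CULTIVARS = ("Merlot", "Cabernet-Sauvignon", "Cabernet franc")


def generate_observations(config: SyntheticStudyConfig, weather: pd.DataFrame,
                          plwp_traj: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Vine-level SWP/PLWP observations with consecutive-day structure.

    For each plot × vine × campaign, one PLWP is measured in the night
    between the two campaign days (shared by both), and SWP on each day is
    the true model's prediction at that PLWP and the day's climate plus
    Gaussian noise (sd ``noise_sd_swp``), truncated below zero.  Rows are
    dropped independently with probability ``missingness``.
    """
    rng = _rng(config.seed + 2 if seed is None else seed)
    form = get_form(config.true_form)
    params = config.resolved_params
    climate = derive_climate_table(weather, config.site)
    climate_by_doy = climate.set_index("doy")
    traj = plwp_traj.set_index(["plot", "doy"])["plwp"]
    lo, hi = config.plwp_range
    rows = []
    for ip in range(config.n_plots):
        plot = f"P{ip + 1:02d}"
        cultivar = _CULTIVARS[ip % len(_CULTIVARS)]
        for iv in range(config.n_vines_per_plot):
            vine = f"V{iv + 1}"
            for ic, (d1, d2) in enumerate(config.campaigns):
                plot_psi = traj.loc[(plot, d1)]
                psi = float(np.clip(plot_psi + rng.normal(0.0, config.noise_sd_plwp), lo, hi))
                for day_no, d in ((1, d1), (2, d2)):
                    crow = climate_by_doy.loc[d]
                    covariate = {
                        "tmax": crow["tmax"], "vpd_max": crow["vpd_max"],
                        "doy": d, "gdd": crow["gdd"],
                    }
                    clim_val = covariate[form.climate] if form.climate else None
                    seas_val = covariate[form.seasonal] if form.seasonal else None
                    mu = predict_swp(form, params, psi, clim_val, seas_val)
                    swp = min(mu + rng.normal(0.0, config.noise_sd_swp), -0.01)
                    rows.append({
                        "plot": plot, "vine": vine, "cultivar": cultivar,
                        "campaign": ic + 1, "day": day_no,
                        "date": crow["date"], "doy": d,
                        "plwp": psi, "swp": float(swp),
                        "tmax": float(crow["tmax"]), "vpd_max": float(crow["vpd_max"]),
                        "et0": float(crow["et0"]), "gdd": float(crow["gdd"]),
                    })
    obs = pd.DataFrame(rows)
    if config.missingness > 0:
        keep = rng.random(len(obs)) >= config.missingness
        obs = obs[keep].reset_index(drop=True)
    return obs


@dataclass
class StudyBundle:
    """A self-consistent synthetic study: weather, derived climate,
    observations and the generating truth."""

    config: SyntheticStudyConfig
    weather: pd.DataFrame
    climate: pd.DataFrame
    observations: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .io import write_observations_csv, write_table, write_weather_csv

        write_weather_csv(self.weather, out / "weather.csv", seed=self.config.seed)
        write_table(self.climate, out / "climate.csv", seed=self.config.seed)
        write_observations_csv(self.observations, out / "observations.csv", seed=self.config.seed)
        (out / "truth.json").write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n")
        return out


def generate_study(config: SyntheticStudyConfig, out_dir=None) -> StudyBundle:
    """Generate a full study bundle (deterministic under ``config.seed``)."""
    weather = generate_weather_season(config)
    climate = derive_climate_table(weather, config.site)
    traj = generate_plwp_trajectories(weather, config)
    obs = generate_observations(config, weather, traj)
    params = config.resolved_params
    truth = {
        "form": get_form(config.true_form).id,
        "params": {k: v for k, v in dataclasses.asdict(params).items() if v is not None},
        "seed": config.seed,
        "noise_sd_swp": config.noise_sd_swp,
        "noise_sd_plwp": config.noise_sd_plwp,
        "n_observations": int(len(obs)),
    }
    bundle = StudyBundle(config=config, weather=weather, climate=climate,
                         observations=obs, truth=truth)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
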