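"""Tabular I/O, run configuration and pipeline orchestration.

CSV is the interchange format: ISO-8601 dates, decimal points, potentials
stored as negative MPa (the physical sign).  Every file the pipeline writes
carries a provenance comment header (package version, seed, config hash) and
floats are written with 6 significant digits, so reruns with the same seed
and configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .climate import Site, derive_climate_table
from .fitting import compare_models, fit_model
from .standardize import evaluate_standardization, pair_consecutive_days, pair_matched_plwp

log = logging.getLogger("swpmodel")

__all__ = [
    "read_weather_csv",
    "write_weather_csv",
    "read_observations_csv",
    "write_observations_csv",
    "write_table",
    "RunConfig",
    "run_pipeline",
]

# external column names <-> internal names
_WEATHER_MAP = {
    "date": "date", "tmax_c": "tmax", "tmin_c": "tmin", "rhmin_pct": "rh_min",
    "rhmax_pct": "rh_max", "radiation_mj_m2": "radiation", "wind_ms": "wind",
    "rain_mm": "rain",
}
_OBS_REQUIRED = ["plot", "vine", "cultivar", "date", "plwp_mpa", "swp_mpa"]
#: tolerance above zero accepted for a (noisy) water potential, MPa
SIGN_TOLERANCE = 0.005


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _parse_dates(df: pd.DataFrame, path) -> pd.Series:
    parsed = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise ValueError(f"{path}: unparseable date {df['date'].iloc[row]!r} at data row {row}")
    return parsed


def read_weather_csv(path) -> pd.DataFrame:
    """Read a daily weather CSV (columns date, tmax_c, tmin_c, rhmin_pct,
    rhmax_pct, radiation_mj_m2, wind_ms, rain_mm) into the internal table."""
    df = _read_csv(path)
    missing = [c for c in _WEATHER_MAP if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing weather columns {missing}")
    out = df[list(_WEATHER_MAP)].rename(columns=_WEATHER_MAP)
    out["date"] = _parse_dates(out, path)
    out = out.sort_values("date", kind="stable").reset_index(drop=True)
    bad = out.index[(out["tmax"] < out["tmin"]) | (out["rh_max"] < out["rh_min"])]
    if len(bad):
        raise ValueError(f"{path}: tmax<tmin or rh_max<rh_min at data row {int(bad[0])}")
    return out


def write_weather_csv(weather: pd.DataFrame, path, **prov) -> None:
    inv = {v: k for k, v in _WEATHER_MAP.items()}
    write_table(weather.rename(columns=inv), path, **prov)


def read_observations_csv(path) -> pd.DataFrame:
    """Read a water-potential observation CSV.

    Requires columns plot, vine, cultivar, date, plwp_mpa, swp_mpa (either
    potential may be empty per row, not both).  Potentials more than
    0.005 MPa above zero, and duplicate (plot, vine, date) rows, are errors.
    """
    df = _read_csv(path)
    missing = [c for c in _OBS_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing observation columns {missing}")
    out = df.rename(columns={"plwp_mpa": "plwp", "swp_mpa": "swp"}).copy()
    out["date"] = _parse_dates(out, path)
    both_empty = out["plwp"].isna() & out["swp"].isna()
    if both_empty.any():
        raise ValueError(
            f"{path}: rows with both potentials empty at data rows "
            f"{list(np.flatnonzero(both_empty.to_numpy())[:5])}"
        )
    for col in ("plwp", "swp"):
        bad = out[col] > SIGN_TOLERANCE
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: positive {col} = {out[col].iloc[row]} MPa at data row {row} "
                f"(beyond the +{SIGN_TOLERANCE} tolerance)"
            )
    dup = out.duplicated(subset=["plot", "vine", "date"], keep=False)
    if dup.any():
        key = out.loc[dup, ["plot", "vine", "date"]].iloc[0].tolist()
        raise ValueError(f"{path}: duplicate observation for (plot, vine, date) = {key}")
    if "doy" not in out.columns:
        out["doy"] = out["date"].dt.dayofyear
    return out.sort_values(["plot", "vine", "date"], kind="stable").reset_index(drop=True)


def write_observations_csv(obs: pd.DataFrame, path, **prov) -> None:
    out = obs.rename(columns={"plwp": "plwp_mpa", "swp": "swp_mpa"})
    write_table(out, path, **prov)


def _provenance_header(**prov) -> str:
    bits = " ".join(f"{k}={v}" for k, v in prov.items())
    return f"# swpmodel {__version__}" + (f" {bits}" if bits else "") + "\n"


def write_table(df: pd.DataFrame, path, **prov) -> None:
    """Write a CSV with a provenance comment header and 6-significant-digit
    floats (deterministic output for identical inputs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_provenance_header(**prov))
        df.to_csv(fh, index=False, float_format="%.6g", date_format="%Y-%m-%d")


@dataclass
class RunConfig:
    """Configuration of one end-to-end pipeline run."""

    weather_csv: str
    observations_csv: str
    out_dir: str
    latitude_deg: float = 45.0
    altitude_m: float = 20.0
    forms: tuple = ("M1", "M2", "M3", "M4", "M5")
    cv_group: str = "plot"
    t_s: float = 30.0
    doy_s: float = 200.0
    max_delta_plwp: float = 0.005
    min_gap_days: int = 7
    seed: int = 0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in raw.items() if k in known}
        kw["extra"] = {k: v for k, v in raw.items() if k not in known}
        if isinstance(kw.get("forms"), list):
            kw["forms"] = tuple(kw["forms"])
        return cls(**kw)

    def config_hash(self) -> str:
        """Hash of the semantic configuration (output location excluded)."""
        sem = dataclasses.asdict(self)
        sem.pop("out_dir")
        blob = json.dumps(sem, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def validate_paths(self) -> None:
        for p in (self.weather_csv, self.observations_csv):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")


def run_pipeline(config: RunConfig) -> Path:
    """Run derive → fit/compare → standardize → validate, writing a run
    directory.  Deterministic under a fixed seed; a stage failure is logged
    and re-raised with the stage name, leaving completed stages intact."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"seed": config.seed, "config": config.config_hash()}
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    stage = "ingest"
    try:
        weather = read_weather_csv(config.weather_csv)
        obs = read_observations_csv(config.observations_csv)
        log.info("ingest: %d weather days, %d observations", len(weather), len(obs))

        stage = "derive"
        site = Site(config.latitude_deg, config.altitude_m)
        climate = derive_climate_table(weather, site)
        write_table(climate, out / "climate.csv", **prov)
        log.info("derive: %d derived climate rows", len(climate))

        stage = "merge"
        merged = obs.merge(
            climate[["doy", "tmax", "vpd_max", "et0", "gdd"]], on="doy", how="left",
            suffixes=("", "_derived"),
        )
        for col in ("tmax", "vpd_max", "gdd"):
            if merged[col].isna().any():
                raise ValueError(f"observations on days without weather coverage ({col})")

        stage = "compare"
        table = compare_models(
            list(config.forms), merged, cv_group=config.cv_group, seed=config.seed
        )
        write_table(table, out / "model_comparison.csv", **prov)
        best_id = table.iloc[0]["form"]
        log.info("compare: %d forms fitted, best by AIC = %s", len(table), best_id)

        stage = "fit"
        best = fit_model(best_id, merged, seed=config.seed)
        params = {k: v for k, v in dataclasses.asdict(best.params).items() if v is not None}
        (out / "best_fit.json").write_text(json.dumps(
            {"form": best.form.id, "params": params, "aic": best.aic, "bic": best.bic,
             "r2": best.r2, "rmse": best.rmse, "n": best.n, "provenance": prov},
            indent=2, sort_keys=True, default=float) + "\n")

        stage = "validate-standardization"
        reports = {}
        consec = pair_consecutive_days(merged)
        matched = pair_matched_plwp(
            merged, max_delta_plwp=config.max_delta_plwp, min_gap_days=config.min_gap_days
        )
        log.info("pairing: %d consecutive-day pairs (%d skipped), %d plwp-matched pairs",
                 len(consec), consec.n_skipped, len(matched))
        if len(consec):
            write_table(consec.pairs, out / "pairs_consecutive.csv", **prov)
            reports["consecutive_eqn1"] = evaluate_standardization(consec, "eqn1").to_dict()
            reports["consecutive_eqn2"] = evaluate_standardization(consec, "eqn2").to_dict()
        if len(matched):
            write_table(matched.pairs, out / "pairs_matched.csv", **prov)
            reports["matched_eqn2"] = evaluate_standardization(matched, "eqn2").to_dict()
        reports["provenance"] = prov
        (out / "standardization_report.json").write_text(
            json.dumps(reports, indent=2, sort_keys=True, default=float) + "\n")
        log.info("done")
        return out
    except Exception as err:
        log.error("stage %s failed: %s", stage, err)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    finally:
        log.removeHandler(handler)
        handler.close()
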