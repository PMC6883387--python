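"""Standardization of stem water potential to reference climatic conditions.

A measured SWP confounds soil water availability with the climate of the
measurement day.  Because models 3 and 5 are algebraically invertible at
fixed PLWP, a measurement taken at (Tmax, DOY) can be mapped to the value the
model predicts under reference conditions (T_s, DOY_s) with soil water status
unchanged:

    temperature only (model 3 form):
        SWP_s = (SWP − c) · (T_s / Tmax)^p + c

    temperature + season (model 5 form):
        SWP_s = (SWP − d·DOY − c) · (T_s / Tmax)^p + d·DOY_s + c

Both are exact inverses of the forward model: predicting at Tmax and then
standardizing to T_s equals predicting at T_s directly.  The amplitude term
(SWP above the dry-limit asymptote c) must be positive; measurements below
the asymptote are flagged NaN with a warning rather than extrapolated.

Also provides the two validation pairings (consecutive-day campaigns and
PLWP-matched pairs within a plot) and the RMSE-improvement report comparing
raw with standardized day-2 values against day-1 observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from sklearn.base import BaseEstimator, TransformerMixin

from .forms import ModelParams, published_params

__all__ = [
    "SWPStandardizer",
    "standardize_swp_temperature",
    "standardize_swp_temperature_doy",
    "pair_consecutive_days",
    "pair_matched_plwp",
    "evaluate_standardization",
    "PairingResult",
    "StandardizationReport",
]


def _check_target_temp(t_s) -> None:
    if np.any(np.asarray(t_s) <= 0):
        raise ValueError("reference temperature must be > 0 °C")
    if np.any((np.asarray(t_s) < 10) | (np.asarray(t_s) > 45)):
        warnings.warn("reference temperature outside the [10, 45] °C sanity band", stacklevel=3)


def standardize_swp_temperature(swp, tmax, t_s, params: ModelParams | None = None):
    """Standardize SWP (MPa) measured at ``tmax`` to reference ``t_s``.

    Uses a model-3-form parameter set (``p``, ``c``); defaults to the
    published model 3 coefficients.  Values at or below the asymptote ``c``
    are flagged NaN with a warning.
    """
    params = published_params("M3") if params is None else params
    if params.p is None:
        raise ValueError("temperature standardization needs a climate exponent p (M3-form params)")
    _check_target_temp(t_s)
    swp = np.asarray(swp, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax <= 0):
        raise ValueError("tmax must be > 0 °C")
    amplitude = swp - params.c
    bad = amplitude <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.count_nonzero(bad))} value(s) at or below the model asymptote "
            f"c = {params.c}; standardized value flagged NaN", stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        out = np.where(bad, np.nan, amplitude) * (np.asarray(t_s, float) / tmax) ** params.p + params.c
    out = np.asarray(out)
    return out if out.ndim else float(out)


def standardize_swp_temperature_doy(swp, tmax, doy, t_s, doy_s, params: ModelParams | None = None):
    """Standardize SWP measured at (``tmax``, ``doy``) to (``t_s``, ``doy_s``).

    Uses a model-5-form parameter set (``p``, ``d``, ``c``); defaults to the
    published model 5 coefficients.  With ``doy_s = doy`` this reduces to the
    temperature-only operation.
    """
    params = published_params("M5") if params is None else params
    if params.p is None or params.d is None:
        raise ValueError("temperature+season standardization needs p and d (M5-form params)")
    _check_target_temp(t_s)
    doy = np.asarray(doy, dtype=float)
    doy_s = np.asarray(doy_s, dtype=float)
    if np.any((doy < 1) | (doy > 366)) or np.any((doy_s < 1) | (doy_s > 366)):
        raise ValueError("doy and doy_s must lie in [1, 366]")
    swp = np.asarray(swp, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if np.any(tmax <= 0):
        raise ValueError("tmax must be > 0 °C")
    amplitude = swp - params.d * doy - params.c
    bad = amplitude <= 0
    if np.any(bad):
        warnings.warn(
            f"{int(np.count_nonzero(bad))} value(s) with non-positive seasonal amplitude; "
            "standardized value flagged NaN", stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        out = (
            np.where(bad, np.nan, amplitude) * (np.asarray(t_s, float) / tmax) ** params.p
            + params.d * doy_s + params.c
        )
    out = np.asarray(out)
    return out if out.ndim else float(out)


class SWPStandardizer(TransformerMixin, BaseEstimator):
    """Transformer mapping measured SWP to reference climatic conditions.

    Parameters
    ----------
    mode : {"eqn2", "eqn1"}
        ``"eqn1"`` standardizes for temperature only (model-3 form);
        ``"eqn2"`` for temperature and seasonality (model-5 form).
    t_s : float, reference maximum temperature (°C).
    doy_s : float, reference day of year (eqn2 only).
    params : ModelParams or None
        Fitted coefficients; None uses the published model 3/5 values.

    ``transform`` takes a DataFrame with columns ``swp``, ``tmax`` (and
    ``doy`` for eqn2) and returns the standardized SWP as an (n, 1) array.
    """

    def __init__(self, mode="eqn2", t_s=30.0, doy_s=200.0, params=None):
        self.mode = mode
        self.t_s = t_s
        self.doy_s = doy_s
        self.params = params

    def fit(self, X=None, y=None):
        if self.mode not in ("eqn1", "eqn2"):
            raise ValueError("mode must be 'eqn1' or 'eqn2'")
        self.params_ = self.params if self.params is not None else published_params(
            "M3" if self.mode == "eqn1" else "M5"
        )
        return self

    def transform(self, X: pd.DataFrame):
        if not hasattr(self, "params_"):
            self.fit()
        need = ["swp", "tmax"] + (["doy"] if self.mode == "eqn2" else [])
        missing = [c for c in need if c not in X.columns]
        if missing:
            raise ValueError(f"standardizer needs columns {missing}")
        if self.mode == "eqn1":
            out = standardize_swp_temperature(X["swp"], X["tmax"], self.t_s, self.params_)
        else:
            out = standardize_swp_temperature_doy(
                X["swp"], X["tmax"], X["doy"], self.t_s, self.doy_s, self.params_
            )
        return np.asarray(out, dtype=float).reshape(-1, 1)


# ---------------------------------------------------------------------------
# validation pairings


@dataclass
class PairingResult:
    """Pair table plus bookkeeping of observations that found no partner."""

    pairs: pd.DataFrame
    kind: str
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.pairs)


_PAIR_COLS = [
    "plot", "vine", "ref_date", "other_date", "gap_days", "delta_plwp",
    "ref_swp", "other_swp", "ref_tmax", "other_tmax", "ref_doy", "other_doy", "plwp",
]


def pair_consecutive_days(data: pd.DataFrame) -> PairingResult:
    """Pair same-vine SWP measurements taken on two consecutive days.

    Field campaigns measure SWP on day 1 and day 2 with PLWP during the
    intervening night, so both members share one PLWP and differ only in the
    day's climate.  The earlier day is the reference.  Observations without a
    next-day partner are skipped and counted.
    """
    df = data.copy()
    df["date"] = pd.to_datetime(df["date"])
    left = df.copy()
    right = df.copy()
    right["date_prev"] = right["date"] - pd.Timedelta(days=1)
    merged = left.merge(
        right, left_on=["plot", "vine", "date"], right_on=["plot", "vine", "date_prev"],
        suffixes=("_ref", "_other"),
    )
    pairs = pd.DataFrame({
        "plot": merged["plot"],
        "vine": merged["vine"],
        "ref_date": merged["date_ref"],
        "other_date": merged["date_other"],
        "gap_days": 1,
        "delta_plwp": merged["plwp_other"] - merged["plwp_ref"],
        "ref_swp": merged["swp_ref"],
        "other_swp": merged["swp_other"],
        "ref_tmax": merged["tmax_ref"],
        "other_tmax": merged["tmax_other"],
        "ref_doy": merged["doy_ref"],
        "other_doy": merged["doy_other"],
        "plwp": merged["plwp_ref"],
    }).sort_values(["plot", "vine", "ref_date"], kind="stable").reset_index(drop=True)
    n_skipped = len(df) - 2 * len(pairs)
    return PairingResult(pairs=pairs, kind="consecutive_day", n_skipped=n_skipped)


def pair_matched_plwp(data: pd.DataFrame, max_delta_plwp: float = 0.005,
                      min_gap_days: int = 7) -> PairingResult:
    """Pair within-plot observations with near-identical PLWP, well apart in time.

    Emits every ordered within-plot pair (earlier observation is the
    reference) whose PLWP values differ by at most ``max_delta_plwp``
    (inclusive) and whose dates are at least ``min_gap_days`` apart.  An
    observation may appear in several pairs; an empty result is allowed.
    """
    df = data.copy()
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for plot, sub in df.groupby("plot"):
        sub = sub.sort_values("date", kind="stable").reset_index(drop=True)
        a = sub.merge(sub, how="cross", suffixes=("_ref", "_other"))
        gap = (a["date_other"] - a["date_ref"]).dt.days
        # inclusive threshold, with headroom for float representation of
        # differences that equal the threshold exactly
        delta_ok = (a["plwp_other"] - a["plwp_ref"]).abs() <= max_delta_plwp + 1e-12
        keep = (gap >= min_gap_days) & delta_ok
        a = a[keep]
        if a.empty:
            continue
        out.append(pd.DataFrame({
            "plot": plot,
            "vine": a["vine_ref"].astype(str) + "|" + a["vine_other"].astype(str),
            "ref_date": a["date_ref"],
            "other_date": a["date_other"],
            "gap_days": (a["date_other"] - a["date_ref"]).dt.days,
            "delta_plwp": a["plwp_other"] - a["plwp_ref"],
            "ref_swp": a["swp_ref"],
            "other_swp": a["swp_other"],
            "ref_tmax": a["tmax_ref"],
            "other_tmax": a["tmax_other"],
            "ref_doy": a["doy_ref"],
            "other_doy": a["doy_other"],
            "plwp": a["plwp_ref"],
        }))
    pairs = (
        pd.concat(out, ignore_index=True).sort_values(
            ["plot", "ref_date", "other_date"], kind="stable"
        ).reset_index(drop=True)
        if out else pd.DataFrame(columns=_PAIR_COLS)
    )
    return PairingResult(pairs=pairs, kind="plwp_matched")


@dataclass
class StandardizationReport:
    """RMSE-improvement summary of a standardization validation."""

    mode: str
    n_pairs: int
    n_flagged: int
    rmse_unstandardized: float
    rmse_standardized: float
    r2_before: float
    r2_after: float

    @property
    def pct_improvement(self) -> float:
        if self.rmse_unstandardized == 0.0:
            return 0.0 if self.rmse_standardized == 0.0 else float("-inf")
        return 100.0 * (self.rmse_unstandardized - self.rmse_standardized) / self.rmse_unstandardized

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_pairs": self.n_pairs,
            "n_flagged": self.n_flagged,
            "rmse_unstandardized": self.rmse_unstandardized,
            "rmse_standardized": self.rmse_standardized,
            "pct_improvement": self.pct_improvement,
            "r2_before": self.r2_before,
            "r2_after": self.r2_after,
        }


def _r2_1to1(x, y) -> float:
    """Squared Pearson correlation of the pair scatter (regression-line r²)."""
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(_stats.pearsonr(x, y).statistic ** 2)


def evaluate_standardization(pairs, mode: str = "eqn1",
                             params: ModelParams | None = None) -> StandardizationReport:
    """Quantify how much standardizing the later member of each pair to the
    reference day's climate tightens agreement with the reference SWP.

    For each pair the "other" SWP is standardized to the reference day's
    Tmax (and DOY for ``mode="eqn2"``); RMSE against the reference SWP is
    reported before and after, with pairs whose standardization was flagged
    (below-asymptote amplitude) excluded from both and counted.
    """
    df = pairs.pairs if isinstance(pairs, PairingResult) else pairs
    if len(df) == 0:
        raise ValueError("empty pair list")
    if mode == "eqn1":
        std = standardize_swp_temperature(
            df["other_swp"], df["other_tmax"], df["ref_tmax"], params
        )
    elif mode == "eqn2":
        std = standardize_swp_temperature_doy(
            df["other_swp"], df["other_tmax"], df["other_doy"],
            df["ref_tmax"], df["ref_doy"], params,
        )
    else:
        raise ValueError("mode must be 'eqn1' or 'eqn2'")
    std = np.asarray(std, dtype=float)
    ok = np.isfinite(std)
    n_flagged = int(np.count_nonzero(~ok))
    if not np.any(ok):
        raise ValueError("all standardized values were flagged")
    ref = df["ref_swp"].to_numpy(float)[ok]
    raw = df["other_swp"].to_numpy(float)[ok]
    std = std[ok]
    return StandardizationReport(
        mode=mode,
        n_pairs=int(np.count_nonzero(ok)),
        n_flagged=n_flagged,
        rmse_unstandardized=float(np.sqrt(np.mean((ref - raw) ** 2))),
        rmse_standardized=float(np.sqrt(np.mean((ref - std) ** 2))),
        r2_before=_r2_1to1(ref, raw),
        r2_after=_r2_1to1(ref, std),
    )
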