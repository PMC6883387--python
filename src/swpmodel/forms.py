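"""The five stem-water-potential model forms and their published coefficients.

All forms are special cases of

    SWP = a · exp(b · PLWP) · X^p + d · S + c

with PLWP the predawn leaf water potential (MPa, ≤ 0), X a daily climate
covariate (VPD_max in kPa or Tmax in °C), and S a seasonal covariate (DOY or
cumulative GDD).  M1 drops the climate term (X^p ≡ 1), M2/M3 add VPD_max or
Tmax, and M4/M5 additionally carry the linear seasonal term.  The exponential
is parameterised exactly as published: a is the amplitude at PLWP = 0 and
b > 0 so that SWP declines as PLWP becomes more negative.  Covariates stay in
their measured units (°C, kPa, days) so published coefficients are directly
usable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "ModelForm",
    "ModelParams",
    "FORMS",
    "get_form",
    "published_params",
    "predict_swp",
    "model_gradient",
    "formula_string",
]


@dataclass(frozen=True)
class ModelForm:
    """Structural description of one model form."""

    id: str
    climate: str | None = None   # None | "vpd_max" | "tmax"
    seasonal: str | None = None  # None | "doy" | "gdd"

    @property
    def param_names(self) -> tuple[str, ...]:
        names = ["a", "b"]
        if self.climate is not None:
            names.append("p")
        if self.seasonal is not None:
            names.append("d")
        names.append("c")
        return tuple(names)

    @property
    def k(self) -> int:
        """Number of free regression parameters."""
        return len(self.param_names)

    @property
    def predictors(self) -> tuple[str, ...]:
        names = ["plwp"]
        if self.climate is not None:
            names.append(self.climate)
        if self.seasonal is not None:
            names.append(self.seasonal)
        return tuple(names)


FORMS: dict[str, ModelForm] = {
    "M1": ModelForm("M1"),
    "M2": ModelForm("M2", climate="vpd_max"),
    "M3": ModelForm("M3", climate="tmax"),
    "M4": ModelForm("M4", climate="vpd_max", seasonal="doy"),
    "M5": ModelForm("M5", climate="tmax", seasonal="doy"),
}


def get_form(form, seasonal: str | None = None) -> ModelForm:
    """Resolve a form id (or pass through a ModelForm), optionally swapping
    the seasonal covariate (``seasonal="gdd"`` gives the GDD variant)."""
    if isinstance(form, ModelForm):
        f = form
    else:
        try:
            f = FORMS[str(form).upper()]
        except KeyError:
            raise ValueError(f"unknown model form {form!r}; expected one of {sorted(FORMS)}") from None
    if seasonal is not None:
        if f.seasonal is None:
            raise ValueError(f"form {f.id} has no seasonal covariate to swap")
        if seasonal not in ("doy", "gdd"):
            raise ValueError("seasonal must be 'doy' or 'gdd'")
        f = replace(f, seasonal=seasonal)
    return f


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of one model form.

    a : amplitude at PLWP = 0, MPa·(covariate unit)^−p
    b : PLWP rate, MPa⁻¹ (> 0)
    p : climate power exponent (None for M1)
    d : seasonal slope, MPa per day or per °C·d (None for M1–M3)
    c : intercept / dry-limit asymptote, MPa
    """

    a: float
    b: float
    c: float
    p: float | None = None
    d: float | None = None
    rmse_train: float | None = field(default=None, compare=False)

    def __post_init__(self):
        for name in ("a", "b", "c", "p", "d"):
            v = getattr(self, name)
            if v is not None and not np.isfinite(v):
                raise ValueError(f"parameter {name} must be finite, got {v}")
        if self.b <= 0:
            warnings.warn("b <= 0: SWP should decline with more negative PLWP", stacklevel=2)
        if self.p is not None and self.p >= 0:
            warnings.warn("p >= 0: published fits all have p < 0", stacklevel=2)
        if self.d is not None and self.d >= 0:
            warnings.warn("d >= 0: published fits all have d < 0", stacklevel=2)

    def to_array(self, form: ModelForm) -> np.ndarray:
        return np.array([getattr(self, n) for n in form.param_names], dtype=float)

    @classmethod
    def from_array(cls, form: ModelForm, theta, rmse_train=None) -> "ModelParams":
        kw = dict(zip(form.param_names, map(float, theta)))
        return cls(rmse_train=rmse_train, **kw)


def published_params(form_id: str) -> ModelParams:
    """Published coefficients for one of M1..M5, loaded from the bundled
    parameter files."""
    form = get_form(form_id)
    with resources.files("swpmodel.params").joinpath(f"{form.id.lower()}.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    if raw.pop("form", form.id).upper() != form.id:
        raise ValueError("parameter file does not match requested form")
    return ModelParams(**raw)


def _check_inputs(form: ModelForm, plwp, climate_value, seasonal_value):
    plwp = np.asarray(plwp, dtype=float)
    if form.climate is not None:
        if climate_value is None:
            raise ValueError(f"form {form.id} needs a {form.climate} value")
        climate_value = np.asarray(climate_value, dtype=float)
        if np.any(climate_value <= 0):
            raise ValueError(f"{form.climate} must be > 0 (power law undefined at 0)")
    if form.seasonal is not None:
        if seasonal_value is None:
            raise ValueError(f"form {form.id} needs a {form.seasonal} value")
        seasonal_value = np.asarray(seasonal_value, dtype=float)
    return plwp, climate_value, seasonal_value


def predict_swp(form, params: ModelParams, plwp, climate_value=None, seasonal_value=None):
    """Evaluate a model form: SWP = a·e^(b·PLWP)·X^p + d·S + c (MPa)."""
    form = get_form(form)
    plwp, x, s = _check_inputs(form, plwp, climate_value, seasonal_value)
    out = params.a * np.exp(params.b * plwp)
    if form.climate is not None:
        out = out * x ** params.p
    if form.seasonal is not None:
        out = out + params.d * s
    out = np.asarray(out + params.c)
    return out if out.ndim else float(out)


def model_gradient(form, params: ModelParams, plwp, climate_value=None, seasonal_value=None):
    """Partial derivatives of the prediction w.r.t. the free parameters.

    Returns an (n, k) array with columns in ``form.param_names`` order.
    """
    form = get_form(form)
    plwp, x, s = _check_inputs(form, plwp, climate_value, seasonal_value)
    plwp = np.atleast_1d(plwp)
    n = plwp.shape[0]
    expb = np.exp(params.b * plwp)
    xp = np.ones(n) if form.climate is None else np.broadcast_to(x, (n,)) ** params.p
    cols = {
        "a": expb * xp,
        "b": params.a * plwp * expb * xp,
        "c": np.ones(n),
    }
    if form.climate is not None:
        cols["p"] = params.a * expb * xp * np.log(np.broadcast_to(x, (n,)))
    if form.seasonal is not None:
        cols["d"] = np.broadcast_to(np.atleast_1d(s), (n,)).astype(float)
    return np.column_stack([cols[name] for name in form.param_names])


def formula_string(form, params: ModelParams) -> str:
    """Human-readable formula with the fitted coefficients substituted."""
    form = get_form(form)
    txt = f"SWP = {params.a:.4g}*exp({params.b:.4g}*PLWP)"
    if form.climate is not None:
        name = {"vpd_max": "VPDmax", "tmax": "Tmax"}[form.climate]
        txt += f"*{name}^{params.p:.4g}"
    if form.seasonal is not None:
        txt += f" - {-params.d:.4g}*{form.seasonal.upper()}" if params.d < 0 else f" + {params.d:.4g}*{form.seasonal.upper()}"
    txt += f" - {-params.c:.4g}" if params.c < 0 else f" + {params.c:.4g}"
    return txt
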