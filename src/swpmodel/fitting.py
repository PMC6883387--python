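"""Nonlinear least-squares fitting and model comparison.

The central object is :class:`SWPModel`, a scikit-learn style regressor that
fits one of the five stem-water-potential forms by trust-region nonlinear
least squares with the analytic Jacobian and a seeded multi-start.  Around it
sit the comparison utilities: Gaussian-likelihood AIC/BIC, pseudo-r² and
RMSE, leave-one-plot-out cross-validation, variance-inflation diagnostics and
per-cultivar grouped fits.

AIC/BIC use the Gaussian log-likelihood with the error variance profiled out
(σ̂² = RSS/n) and σ counted in the parameter total, so for k regression
coefficients::

    AIC = n·ln(2π·RSS/n) + n + 2(k+1)
    BIC = n·ln(2π·RSS/n) + n + ln(n)·(k+1)

the same convention as R's ``AIC()`` on an ``nls`` fit.  Absolute values
depend on the convention; differences between models do not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import LeaveOneGroupOut
from sklearn.utils.validation import check_is_fitted

from .forms import ModelForm, ModelParams, formula_string, get_form, model_gradient, predict_swp

__all__ = [
    "SWPModel",
    "FitResult",
    "CVResult",
    "GroupedFitResult",
    "fit_model",
    "information_criteria",
    "goodness_of_fit",
    "leave_one_plot_out_cv",
    "variance_inflation",
    "compare_models",
    "grouped_fit",
]


def information_criteria(n, k: int | None = None, rss: float | None = None) -> tuple[float, float]:
    """Gaussian AIC and BIC from sample size, parameter count and RSS.

    ``k`` counts the regression coefficients; the error standard deviation is
    counted on top (k+1 in the penalty).  ``rss = 0`` is flagged and yields
    −∞ for both criteria.  Accepts either ``(n, k, rss)`` or a fitted
    result object with those attributes.
    """
    if k is None and rss is None:
        n, k, rss = n.n, n.k, n.rss
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        warnings.warn("rss = 0: information criteria are -inf", stacklevel=2)
        return -math.inf, -math.inf
    core = n * math.log(2.0 * math.pi * rss / n) + n
    return core + 2.0 * (k + 1), core + math.log(n) * (k + 1)


def goodness_of_fit(observed, predicted) -> tuple[float, float]:
    """Pseudo-r² (1 − RSS/TSS about the observed mean) and RMSE = √(RSS/n)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    rss = float(np.sum((observed - predicted) ** 2))
    tss = float(np.sum((observed - observed.mean()) ** 2))
    rmse = math.sqrt(rss / observed.size)
    if tss == 0.0:
        warnings.warn("zero total sum of squares: r2 undefined", stacklevel=2)
        return math.nan, rmse
    return 1.0 - rss / tss, rmse


class SWPModel(RegressorMixin, BaseEstimator):
    """Nonlinear stem-water-potential regressor, SWP = a·e^(b·PLWP)·X^p + d·S + c.

    Parameters
    ----------
    form : str or ModelForm, default "M5"
        One of M1..M5 (see :mod:`swpmodel.forms`).
    seasonal_covariate : {"doy", "gdd"} or None
        Override the seasonal covariate of M4/M5 (``"gdd"`` fits the
        growing-degree-day variant).
    n_starts : int, default 5
        Multi-start count: the data-driven initial point plus jittered
        restarts, keeping the best converged solution.
    random_state : int, default 0
        Seed for the restart jitter.
    max_iter : int, default 500
        Cap on optimizer iterations per start.
    tol : float, default 1e-10
        Cost-reduction (and step/gradient) tolerance of the optimizer.

    Attributes (after ``fit``)
    --------------------------
    form_ : resolved ModelForm; params_ : fitted ModelParams;
    rss_, rmse_, r2_, aic_, bic_ : training statistics;
    residuals_ : observed − fitted; converged_ : bool; n_iter_ : evaluations.

    ``X`` may be a DataFrame carrying the form's predictor columns
    (``plwp`` plus ``tmax``/``vpd_max`` and ``doy``/``gdd`` as required) or a
     2-D array with those columns in that order.
    """

    def __init__(self, form="M5", seasonal_covariate=None, n_starts=5,
                 random_state=0, max_iter=500, tol=1e-10):
        self.form = form
        self.seasonal_covariate = seasonal_covariate
        self.n_starts = n_starts
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    # -- helpers -----------------------------------------------------------
    def _resolve_form(self) -> ModelForm:
        return get_form(self.form, seasonal=self.seasonal_covariate)

    def _design(self, X, form: ModelForm):
        """Extract (plwp, climate, seasonal) arrays from X."""
        names = form.predictors
        if isinstance(X, pd.DataFrame):
            missing = [c for c in names if c not in X.columns]
            if missing:
                raise ValueError(f"form {form.id} needs predictor columns {missing}")
            mat = X[list(names)].to_numpy(dtype=float)
        else:
            mat = np.asarray(X, dtype=float)
            if mat.ndim == 1:
                mat = mat[:, None]
            if mat.shape[1] < len(names):
                raise ValueError(
                    f"form {form.id} needs {len(names)} predictor columns {names}, got {mat.shape[1]}"
                )
            mat = mat[:, : len(names)]
        if not np.all(np.isfinite(mat)):
            raise ValueError("non-finite predictor values")
        plwp = mat[:, 0]
        climate = mat[:, 1] if form.climate is not None else None
        seasonal = mat[:, len(names) - 1] if form.seasonal is not None else None
        if climate is not None and np.any(climate <= 0):
            raise ValueError(f"{form.climate} must be strictly positive")
        return plwp, climate, seasonal

    def _initial_theta(self, form: ModelForm, plwp, y) -> np.ndarray:
        # log-linearization: SWP - c ~ a*exp(b*PLWP)  =>  ln(SWP - c) ~ ln a + b*PLWP
        c0 = float(np.min(y)) - 0.1
        amp = np.maximum(y - c0, 1e-6)
        slope, logint = np.polyfit(plwp, np.log(amp), 1)
        b0 = float(np.clip(slope, 0.1, 20.0))
        a0 = float(np.clip(np.max(y) - c0, 1e-3, None))
        init = {"a": a0, "b": b0, "p": -0.5, "d": -0.005, "c": c0}
        return np.array([init[n] for n in form.param_names])

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y):
        form = self._resolve_form()
        y = np.asarray(y, dtype=float).ravel()
        plwp, climate, seasonal = self._design(X, form)
        n, k = y.size, form.k
        if plwp.size != n:
            raise ValueError("X and y have inconsistent lengths")
        if n <= k + 1:
            raise ValueError(f"need more than k+1 = {k + 1} observations, got {n}")
        if np.ptp(plwp) < 1e-12:
            raise ValueError("PLWP is constant: a and b are not separately identifiable")

        # raw-theta evaluation: optimizer iterates may violate the sign
        # conventions that ModelParams enforces on a finished fit
        names = form.param_names
        logx = np.log(climate) if climate is not None else None

        def unpack(theta):
            d = dict(zip(names, theta))
            return d["a"], d["b"], d.get("p"), d.get("d"), d["c"]

        def resid(theta):
            a, b, p, dd, c = unpack(theta)
            with np.errstate(over="ignore", invalid="ignore"):
                out = a * np.exp(np.minimum(b * plwp, 50.0))
                if climate is not None:
                    out = out * np.exp(p * logx)
                if seasonal is not None:
                    out = out + dd * seasonal
            return out + c - y

        def jac(theta):
            a, b, p, dd, c = unpack(theta)
            with np.errstate(over="ignore", invalid="ignore"):
                expb = np.exp(np.minimum(b * plwp, 50.0))
                xp = np.exp(p * logx) if climate is not None else np.ones(n)
                cols = {"a": expb * xp, "b": a * plwp * expb * xp, "c": np.ones(n)}
                if climate is not None:
                    cols["p"] = a * expb * xp * logx
                if seasonal is not None:
                    cols["d"] = seasonal
            return np.column_stack([cols[m] for m in names])

        theta0 = self._initial_theta(form, plwp, y)
        rng = np.random.default_rng(self.random_state)
        best = None
        with warnings.catch_warnings():
            # b>0/p-sign warnings from intermediate iterates are not informative
            warnings.simplefilter("ignore")
            for s in range(max(1, int(self.n_starts))):
                start = theta0 if s == 0 else theta0 * (1.0 + 0.3 * rng.standard_normal(k))
                start = start.copy()
                start[form.param_names.index("b")] = abs(start[form.param_names.index("b")]) or 0.1
                try:
                    sol = least_squares(
                        resid, start, jac=jac, method="trf",
                        ftol=self.tol, xtol=self.tol, gtol=self.tol,
                        max_nfev=self.max_iter, x_scale="jac",
                    )
                except (ValueError, FloatingPointError):
                    continue
                if np.all(np.isfinite(sol.x)) and (best is None or sol.cost < best.cost):
                    best = sol
        if best is None:
            raise RuntimeError(f"fit of {form.id} failed to converge from any start")

        self.form_ = form
        self.params_ = ModelParams.from_array(form, best.x)
        self.coef_ = best.x.copy()
        self.n_ = n
        self.k_ = k
        fitted = y + best.fun  # resid() returns predicted - observed
        self.residuals_ = y - fitted
        self.rss_ = float(2.0 * best.cost)
        self.r2_, self.rmse_ = goodness_of_fit(y, fitted)
        self.aic_, self.bic_ = information_criteria(n, k, self.rss_)
        self.converged_ = bool(best.status > 0)
        self.n_iter_ = int(best.nfev)
        self.n_features_in_ = len(form.predictors)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        plwp, climate, seasonal = self._design(X, self.form_)
        out = predict_swp(self.form_, self.params_, plwp, climate, seasonal)
        return np.atleast_1d(out)

    def result(self) -> "FitResult":
        check_is_fitted(self, "params_")
        return FitResult(
            form=self.form_, params=self.params_, n=self.n_, k=self.k_,
            rss=self.rss_, aic=self.aic_, bic=self.bic_, r2=self.r2_,
            rmse=self.rmse_, residuals=self.residuals_.copy(),
            converged=self.converged_, n_iterations=self.n_iter_,
        )


@dataclass
class FitResult:
    """Summary of one nonlinear least-squares fit."""

    form: ModelForm
    params: ModelParams
    n: int
    k: int
    rss: float
    aic: float
    bic: float
    r2: float
    rmse: float
    residuals: np.ndarray
    converged: bool
    n_iterations: int

    @property
    def formula(self) -> str:
        return formula_string(self.form, self.params)


@dataclass
class CVResult:
    """Leave-one-plot-out cross-validation summary (mean ± sd of fold RMSEs)."""

    fold_rmse: dict
    failed_folds: list = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.fold_rmse.values())))

    @property
    def sd(self) -> float:
        vals = list(self.fold_rmse.values())
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else math.nan

    @property
    def n_folds(self) -> int:
        return len(self.fold_rmse)


def _split_xy(data: pd.DataFrame, form: ModelForm):
    missing = [c for c in (*form.predictors, "swp") if c not in data.columns]
    if missing:
        raise ValueError(f"data lacks required columns {missing} for form {form.id}")
    return data[list(form.predictors)], data["swp"].to_numpy(float)


def fit_model(form, data: pd.DataFrame, seasonal=None, n_starts=5, seed=0) -> FitResult:
    """Fit one form to an observation table (columns ``swp`` + predictors)."""
    form = get_form(form, seasonal=seasonal)
    X, y = _split_xy(data, form)
    est = SWPModel(form=form, n_starts=n_starts, random_state=seed).fit(X, y)
    return est.result()


def leave_one_plot_out_cv(form, data: pd.DataFrame, group_key="plot",
                          seasonal=None, n_starts=5, seed=0) -> CVResult:
    """Leave-one-plot-out CV: each plot is held out once; RMSE per fold.

    A fold whose training set is degenerate is marked failed and excluded
    with a warning.
    """
    form = get_form(form, seasonal=seasonal)
    groups = data[group_key].to_numpy()
    X, y = _split_xy(data, form)
    splitter = LeaveOneGroupOut()
    fold_rmse, failed = {}, []
    for train_idx, test_idx in splitter.split(X, y, groups):
        held = groups[test_idx[0]]
        try:
            est = SWPModel(form=form, n_starts=n_starts, random_state=seed)
            est.fit(X.iloc[train_idx], y[train_idx])
            pred = est.predict(X.iloc[test_idx])
            fold_rmse[held] = float(np.sqrt(np.mean((y[test_idx] - pred) ** 2)))
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"fold {held!r} failed and was excluded: {err}")
            failed.append(held)
    if not fold_rmse:
        raise RuntimeError("every cross-validation fold failed")
    return CVResult(fold_rmse=fold_rmse, failed_folds=failed)


def variance_inflation(data: pd.DataFrame, form, seasonal=None) -> dict[str, float]:
    """Variance inflation factor of each predictor of a form.

    VIF_j = 1/(1 − R²_j) from regressing predictor j on the others (with
    intercept).  Perfect collinearity is reported as ``inf``.
    """
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    from statsmodels.tools import add_constant

    form = get_form(form, seasonal=seasonal)
    preds = list(form.predictors)
    if len(preds) < 2:
        raise ValueError(f"form {form.id} has a single predictor; VIF needs at least 2")
    design = add_constant(data[preds].to_numpy(float), has_constant="add")
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for j, name in enumerate(preds):
            v = variance_inflation_factor(design, j + 1)
            out[name] = float(v) if np.isfinite(v) else math.inf
    return out


def compare_models(forms, data: pd.DataFrame, cv_group="plot", seasonal=None,
                   n_starts=5, seed=0, cv=True) -> pd.DataFrame:
    """Fit several forms and tabulate AIC, BIC, r², training and CV RMSE.

    One row per form, sorted by AIC ascending; per-form failures are recorded
    in the row's ``error`` column instead of aborting the comparison.
    """
    rows = []
    for f in forms:
        form = get_form(f, seasonal=seasonal)
        row = {"form": form.id, "seasonal": form.seasonal, "aic": math.nan}
        try:
            fit = fit_model(form, data, n_starts=n_starts, seed=seed)
            row.update(
                formula=fit.formula, k=fit.k, aic=fit.aic, bic=fit.bic,
                r2=fit.r2, rmse_train=fit.rmse, error="",
                **{f"param_{n}": getattr(fit.params, n) for n in form.param_names},
            )
            if cv and cv_group in data.columns and data[cv_group].nunique() > 1:
                cvres = leave_one_plot_out_cv(
                    form, data, group_key=cv_group, n_starts=n_starts, seed=seed
                )
                row.update(rmse_cv_mean=cvres.mean, rmse_cv_sd=cvres.sd, n_folds=cvres.n_folds)
        except (ValueError, RuntimeError) as err:
            row.update(error=str(err))
        rows.append(row)
    table = pd.DataFrame(rows)
    return table.sort_values("aic", na_position="last").reset_index(drop=True)


@dataclass
class GroupedFitResult:
    """Per-group fits of one form plus the pooled-vs-global RMSE comparison."""

    per_group: dict
    skipped: list
    pooled_rmse: float
    global_rmse: float

    @property
    def rmse_delta(self) -> float:
        """global RMSE − pooled grouped RMSE (positive: grouping helps)."""
        return self.global_rmse - self.pooled_rmse


def grouped_fit(form, data: pd.DataFrame, group_key="cultivar",
                seasonal=None, n_starts=5, seed=0) -> GroupedFitResult:
    """Fit one form separately per group (default cultivar) and pool RMSE.

    Groups too small to fit are skipped with a warning.  Pooled RMSE across
    grouped fits cannot exceed the all-data training RMSE (extra parameters
    cannot worsen the training fit), up to numerical tolerance.
    """
    form = get_form(form, seasonal=seasonal)
    global_fit = fit_model(form, data, n_starts=n_starts, seed=seed)
    per_group, skipped = {}, []
    sse, n_used = 0.0, 0
    for name, sub in data.groupby(group_key):
        if len(sub) <= form.k + 1:
            warnings.warn(f"group {name!r} has too few observations; skipped")
            skipped.append(name)
            continue
        try:
            res = fit_model(form, sub, n_starts=n_starts, seed=seed)
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"group {name!r} failed to fit; skipped: {err}")
            skipped.append(name)
            continue
        per_group[name] = res
        sse += res.rss
        n_used += res.n
    if not per_group:
        raise RuntimeError("no group could be fitted")
    return GroupedFitResult(
        per_group=per_group, skipped=skipped,
        pooled_rmse=math.sqrt(sse / n_used), global_rmse=global_fit.rmse,
    )
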