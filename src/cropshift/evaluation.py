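"""Predictive comparison of the yield models on a temporal holdout.

R-squared follows the unadjusted definition

    R^2 = 1 - sum (y_i - yhat_i)^2 / sum (y_i - ybar)^2

over county-year observations of log yield, with ybar the average of the
observations being evaluated. It is unbounded below and reported as-is:
strongly negative values are the signature of an over-fitted model
extrapolating outside its training years. Cross-validation uses a single
temporal split (fit on years <= split_year, evaluate after), mirroring
the forward-prediction use of the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import hier, ols

__all__ = ["r_squared", "temporal_split", "run_comparison", "EvalResult"]

BAYES_MODELS = {"bayes1": "county", "bayes2": "uniform"}


def r_squared(y, yhat, baseline_mean: float | None = None) -> float:
    """Unadjusted R^2 of predictions ``yhat`` against observations ``y``.

    ``baseline_mean`` overrides the mean used in the denominator (e.g. a
    training-set mean under cross-validation); by default the mean of
    ``y`` itself is used.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) < 2:
        raise ValueError("y and yhat must be equal-length 1-d arrays of length >= 2")
    ybar = float(np.mean(y)) if baseline_mean is None else float(baseline_mean)
    denom = float(np.sum((y - ybar) ** 2))
    if denom == 0.0:
        raise ValueError("constant observations: R^2 undefined (zero denominator)")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


def temporal_split(panel: pd.DataFrame, split_year: int = 1994) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact partition of a panel into years <= split_year and years after."""
    train = panel[panel["year"] <= split_year]
    test = panel[panel["year"] > split_year]
    if train.empty or test.empty:
        raise ValueError(
            f"temporal split at {split_year} leaves an empty side "
            f"(years {panel['year'].min()}-{panel['year'].max()})"
        )
    return train.reset_index(drop=True), test.reset_index(drop=True)


@dataclass
class EvalResult:
    crop: str
    model: str
    scope: str  # "all-years" or "cv"
    r_squared: float
    n_obs: int


def _bayes_r2(panel_fit, panel_eval, covariates, label, sampler, baseline_mean):
    spec = hier.ModelSpec(crop=str(panel_fit["crop"].iloc[0]), variance_mode=BAYES_MODELS[label])
    model = hier.build_model(panel_fit, covariates, spec)
    draws = hier.fit(model, **sampler)
    yhat = hier.point_predict(draws, panel_eval, covariates=covariates)
    return r_squared(panel_eval["log_yield"].to_numpy(), yhat, baseline_mean)


def _ols_r2(panel_fit, panel_eval, covariates, label, crop, baseline_mean):
    spec = ols.OlsSpec(name=label, crop=crop)
    fit = ols.fit_ols(panel_fit, covariates, spec)
    yhat = ols.predict_ols(fit, panel_eval, covariates)
    return r_squared(panel_eval["log_yield"].to_numpy(), yhat, baseline_mean)


def run_comparison(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    models: list[str] | None = None,
    split_year: int | None = None,
    scopes: tuple[str, ...] = ("all-years", "cv"),
    sampler: dict | None = None,
    cv_baseline: str = "test",
    seed: int = 0,
) -> pd.DataFrame:
    """The model-comparison grid: one R^2 per (crop, model, scope).

    ``models`` may mix ``ols1..ols4`` and ``bayes1``/``bayes2``. Under
    ``scope="cv"`` all models are fit on years up to ``split_year``
    (default: the 75% quantile of year labels) and evaluated after it;
    ``cv_baseline`` picks which observations define ybar in the
    denominator ("test", the default, or "train"). Bayesian predictions
    evaluate the mean function at the averaged parameter draw.
    """
    models = models or ["ols1", "ols2", "ols3", "ols4", "bayes1", "bayes2"]
    sampler = dict(sampler or {"chains": 2, "warmup": 500, "draws": 500})
    sampler.setdefault("seed", seed)
    if split_year is None and "cv" in scopes:
        years = np.sort(panel["year"].unique())
        split_year = int(years[int(0.75 * len(years)) - 1])
    results: list[EvalResult] = []
    for crop in sorted(panel["crop"].unique()):
        sub = panel[panel["crop"] == crop]
        for scope in scopes:
            if scope == "all-years":
                fit_p, eval_p, baseline = sub, sub, None
            elif scope == "cv":
                fit_p, eval_p = temporal_split(sub, split_year)
                baseline = (
                    float(fit_p["log_yield"].mean()) if cv_baseline == "train" else None
                )
            else:
                raise ValueError(f"unknown scope {scope!r}")
            for label in models:
                try:
                    if label in BAYES_MODELS:
                        r2 = _bayes_r2(fit_p, eval_p, covariates, label, sampler, baseline)
                    elif label in ols.VALID_SPECS:
                        r2 = _ols_r2(fit_p, eval_p, covariates, label, crop, baseline)
                    else:
                        raise ValueError(f"unknown model label {label!r}")
                except ValueError as err:
                    raise ValueError(f"{crop}/{label}/{scope}: {err}") from err
                results.append(EvalResult(crop, label, scope, r2, len(eval_p)))
    return pd.DataFrame([vars(r) for r in results])
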