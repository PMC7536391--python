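"""The four least-squares comparison specifications for the yield model.

The grid crosses intercept and slope structure:

* ``ols1`` — one intercept, four national slopes.
* ``ols2`` — county fixed-effect intercepts, four national slopes.
* ``ols3`` — covariate-interacted intercept and slopes (fully
  covariate-driven: predicts in counties never observed).
* ``ols4`` — county fixed-effect intercepts with covariate-interacted
  slopes. (Covariate main effects on the intercept would be collinear
  with the county indicators, so the intercept block is indicators only.)

These are the empirical baselines against which the partial-pooling
model's out-of-sample behaviour is measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .covariates import COVARIATE_NAMES, CovariateScaler
from .hier import PREDICTOR_NAMES

__all__ = ["OlsSpec", "OlsFit", "build_design", "fit_ols", "predict_ols", "VALID_SPECS"]

VALID_SPECS = {
    "ols1": ("uniform", "uniform"),
    "ols2": ("county", "uniform"),
    "ols3": ("interacted", "interacted"),
    "ols4": ("county", "interacted"),
}


@dataclass(frozen=True)
class OlsSpec:
    name: str
    crop: str

    def __post_init__(self) -> None:
        if self.name not in VALID_SPECS:
            raise ValueError(f"spec must be one of {sorted(VALID_SPECS)}, got {self.name!r}")

    @property
    def intercepts(self) -> str:
        return VALID_SPECS[self.name][0]

    @property
    def coefficients(self) -> str:
        return VALID_SPECS[self.name][1]


@dataclass
class OlsFit:
    spec: OlsSpec
    coef: np.ndarray
    columns: list[str]
    counties: np.ndarray  # counties seen at fit time (for county intercepts)
    scaler: CovariateScaler
    resid_var: float


def _design(
    rows: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: OlsSpec,
    scaler: CovariateScaler,
    counties: np.ndarray,
) -> tuple[np.ndarray, list[str]]:
    n = len(rows)
    X = rows[list(PREDICTOR_NAMES)].to_numpy(dtype=float)
    cov = covariates.set_index("county_id")
    missing = [c for c in rows["county_id"].unique() if c not in cov.index]
    if missing:
        raise ValueError(f"counties missing from covariate table: {missing[:10]}")
    covrows = cov.loc[rows["county_id"]].reset_index()
    Wz = scaler.transform(covrows, spec.crop)  # (n, 6)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if spec.intercepts == "uniform":
        blocks.append(np.ones((n, 1)))
        names.append("const")
    elif spec.intercepts == "interacted":
        blocks.append(np.ones((n, 1)))
        names.append("const")
        blocks.append(Wz)
        names.extend([f"covar:{c}" for c in (*COVARIATE_NAMES, "irrigation")])
    else:  # county indicators
        pos = {cid: j for j, cid in enumerate(counties)}
        idx = rows["county_id"].map(pos)
        if idx.isna().any():
            unseen = sorted(rows.loc[idx.isna(), "county_id"].unique())
            raise KeyError(
                f"county-intercept spec {spec.name} cannot predict for unseen counties: {unseen[:10]}"
            )
        ind = np.zeros((n, len(counties)))
        ind[np.arange(n), idx.to_numpy(dtype=int)] = 1.0
        blocks.append(ind)
        names.extend([f"county:{cid}" for cid in counties])
    blocks.append(X)
    names.extend([f"x:{p}" for p in PREDICTOR_NAMES])
    if spec.coefficients == "interacted":
        inter = (X[:, :, None] * Wz[:, None, :]).reshape(n, -1)
        blocks.append(inter)
        names.extend(
            [
                f"x:{p}*covar:{c}"
                for p in PREDICTOR_NAMES
                for c in (*COVARIATE_NAMES, "irrigation")
            ]
        )
    return np.hstack(blocks), names


def build_design(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: OlsSpec,
    scaler: CovariateScaler | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray, CovariateScaler]:
    """Design matrix and response for one spec; returns (X, y, names, counties, scaler)."""
    rows = panel[panel["crop"] == spec.crop]
    if rows.empty:
        raise ValueError(f"panel has no rows for crop {spec.crop!r}")
    counties = np.sort(rows["county_id"].unique())
    if scaler is None:
        cov = covariates.set_index("county_id").loc[counties].reset_index()
        scaler = CovariateScaler.fit(cov, [spec.crop])
    X, names = _design(rows, covariates, spec, scaler, counties)
    y = rows["log_yield"].to_numpy(dtype=float)
    if X.shape[0] < X.shape[1]:
        raise ValueError(f"{spec.name}: fewer rows ({X.shape[0]}) than columns ({X.shape[1]})")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the dependent columns via pivoted QR
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        offending = [names[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design ({rank} < {X.shape[1]}); dependent columns: {offending}")
    return X, y, names, counties, scaler


def fit_ols(
    panel: pd.DataFrame,
    covariates: pd.DataFrame,
    spec: OlsSpec,
    scaler: CovariateScaler | None = None,
) -> OlsFit:
    """Least-squares fit of one specification (singular designs rejected)."""
    X, y, names, counties, scaler = build_design(panel, covariates, spec, scaler)
    if X.shape[0] < X.shape[1]:
        raise ValueError(f"{spec.name}: fewer rows ({X.shape[0]}) than columns ({X.shape[1]})")
    coef, _, _, _ = linalg.lstsq(X, y)
    resid = y - X @ coef
    dof = max(X.shape[0] - X.shape[1], 1)
    return OlsFit(
        spec=spec,
        coef=coef,
        columns=names,
        counties=counties,
        scaler=scaler,
        resid_var=float(resid @ resid) / dof,
    )


def predict_ols(
    fit: OlsFit,
    rows: pd.DataFrame,
    covariates: pd.DataFrame,
    unseen_county: str = "error",
) -> np.ndarray:
    """Linear prediction for panel rows.

    Under county-intercept specs a county absent from the fit has no
    intercept; the default is to raise. ``unseen_county="mean"``
    substitutes the average fitted county intercept instead (flagged
    behaviour, never a silent zero).
    """
    rows = rows[rows["crop"] == fit.spec.crop] if "crop" in rows.columns else rows
    if fit.spec.intercepts != "county" or unseen_county == "error":
        X, _ = _design(rows, covariates, fit.spec, fit.scaler, fit.counties)
        return X @ fit.coef
    if unseen_county != "mean":
        raise ValueError("unseen_county must be 'error' or 'mean'")
    known = set(fit.counties)
    seen_mask = rows["county_id"].isin(known).to_numpy()
    out = np.empty(len(rows))
    if seen_mask.any():
        Xs, _ = _design(rows[seen_mask], covariates, fit.spec, fit.scaler, fit.counties)
        out[seen_mask] = Xs @ fit.coef
    if (~seen_mask).any():
        sub = rows[~seen_mask].copy()
        n_cty = len(fit.counties)
        mean_intercept = float(np.mean(fit.coef[:n_cty]))
        Xp = sub[list(PREDICTOR_NAMES)].to_numpy(dtype=float)
        pred = mean_intercept + Xp @ fit.coef[n_cty : n_cty + 4]
        if fit.spec.coefficients == "interacted":
            cov = covariates.set_index("county_id").loc[sub["county_id"]].reset_index()
            Wz = fit.scaler.transform(cov, fit.spec.crop)
            inter = (Xp[:, :, None] * Wz[:, None, :]).reshape(len(sub), -1)
            pred = pred + inter @ fit.coef[n_cty + 4 :]
        out[~seen_mask] = pred
    return out
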