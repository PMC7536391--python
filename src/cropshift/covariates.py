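"""Shared handling of the six county-level constant covariates.

The coefficient model uses five bioclimatic covariates common to all
crops plus a per-crop irrigation fraction. Covariates are z-scored
(mean 0, SD 1 across the counties of the fitted table) before entering
any model, for prior comparability and conditioning; the scaler records
the transformation so that generators and fitted models agree on the
scale and predictions can be made for new counties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COVARIATE_NAMES = (
    "mean_temp",
    "isothermality",
    "temp_seasonality",
    "annual_precip",
    "precip_seasonality",
)
# the sixth covariate is the crop-specific column f"irrigation_{crop}"


def covariate_columns(crop: str) -> list[str]:
    return [*COVARIATE_NAMES, f"irrigation_{crop}"]


def covariate_matrix(covariates: pd.DataFrame, crop: str) -> np.ndarray:
    """Raw (n_counties, 6) matrix for one crop; errors on missing columns."""
    cols = covariate_columns(crop)
    missing = [c for c in cols if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table missing columns: {missing}")
    mat = covariates[cols].to_numpy(dtype=float)
    if np.isnan(mat).any():
        bad = covariates.loc[np.isnan(mat).any(axis=1), "county_id"].tolist()
        raise ValueError(f"missing covariate values for counties: {bad[:10]}")
    return mat


@dataclass
class CovariateScaler:
    """Per-crop z-scoring of the six covariates, fitted once and reused."""

    means: dict[str, np.ndarray]  # crop -> (6,)
    sds: dict[str, np.ndarray]

    @classmethod
    def fit(cls, covariates: pd.DataFrame, crops) -> "CovariateScaler":
        means, sds = {}, {}
        for crop in crops:
            mat = covariate_matrix(covariates, crop)
            mu = mat.mean(axis=0)
            sd = mat.std(axis=0, ddof=1)
            if np.any(sd <= 0):
                cols = covariate_columns(crop)
                bad = [cols[j] for j in np.where(sd <= 0)[0]]
                raise ValueError(f"zero-variance covariate(s) for {crop}: {bad}")
            means[crop], sds[crop] = mu, sd
        return cls(means=means, sds=sds)

    def transform(self, covariates: pd.DataFrame, crop: str) -> np.ndarray:
        mat = covariate_matrix(covariates, crop)
        return (mat - self.means[crop][None, :]) / self.sds[crop][None, :]
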