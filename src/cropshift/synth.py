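"""Synthetic county panels with the generative structure the yield model assumes.

The generator emulates the shape of a multi-crop US county panel: a table
of six constant covariates per county (five bioclimatic summaries plus a
per-crop irrigation fraction), county-level intercepts and weather
coefficients drawn from the covariate-driven hierarchical model, yearly
weather predictors correlated with county climate, log-yields drawn from
the linear likelihood, an economics table (price, cultivation cost,
baseline planted area, designated observed crop), and shifted-climate
scenario panels.

Two generator modes:

* ``"faithful"`` — county coefficients are exactly normal around their
  covariate-implied means, i.e. the joint distribution matches the fitted
  hierarchical model's likelihood. Used for parameter-recovery and
  calibration checks.
* ``"misspecified"`` — additional heavy-tailed (Student-t) idiosyncratic
  noise is added to county coefficients beyond the covariate model,
  producing the regime in which flexible fixed-effects regressions
  over-fit while partial pooling remains robust. (Extra *normal* noise
  would still lie inside the fitted model class, so a heavy-tailed
  deviation is used to give the contrast content.)

Every distributional constant lives in :class:`GeneratorConfig`; nothing
is hard-coded in the sampling routines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariates import COVARIATE_NAMES, CovariateScaler, covariate_matrix

__all__ = [
    "GeneratorConfig",
    "CropHyper",
    "CropTruth",
    "TrueParameters",
    "PanelResult",
    "ClimateScenario",
    "generate_counties",
    "generate_true_params",
    "generate_panel",
    "generate_economics",
    "generate_scenario",
    "simulate",
]

CROPS = ("barley", "corn", "cotton", "rice", "soybeans", "wheat")


def _default_base_log_yield() -> dict[str, float]:
    # roughly log of typical 2000s US yields in each crop's customary unit/acre
    return {
        "barley": 4.1,
        "corn": 5.0,
        "cotton": 6.7,
        "rice": 8.9,
        "soybeans": 3.7,
        "wheat": 3.7,
    }


def _default_prices() -> dict[str, float]:
    # USD per yield unit, 2010-era magnitudes
    return {
        "barley": 4.7,
        "corn": 3.8,
        "cotton": 0.65,
        "rice": 0.10,
        "soybeans": 9.5,
        "wheat": 5.1,
    }


def _default_costs() -> dict[str, float]:
    # USD per acre cultivation costs; barley cheapest, rice most expensive
    return {
        "barley": 123.0,
        "corn": 400.0,
        "cotton": 380.0,
        "rice": 499.0,
        "soybeans": 220.0,
        "wheat": 125.0,
    }


@dataclass
class GeneratorConfig:
    """All constants of the synthetic world, in one place.

    Covariate distributions target realistic contiguous-US ranges (county
    mean temperature ~5-25 degC, annual precipitation a few hundred to
    ~1500 mm) with a positive temperature-precipitation correlation.
    Coefficient magnitudes are on the standardized-predictor scale, so
    e.g. ``a_edd = -0.10`` means one SD of extreme degree-days costs 10%
    of yield in the average county.
    """

    crops: tuple[str, ...] = CROPS
    mode: str = "faithful"  # or "misspecified"
    base_year: int = 1950

    # --- county covariates ---
    mean_temp_mean: float = 15.0
    mean_temp_sd: float = 5.0
    annual_precip_mean: float = 900.0
    annual_precip_sd: float = 250.0
    temp_precip_corr: float = 0.35
    isothermality_mean: float = 0.45
    isothermality_sd: float = 0.08
    temp_seasonality_mean: float = 8.0
    temp_seasonality_sd: float = 2.0
    precip_seasonality_mean: float = 30.0
    precip_seasonality_sd: float = 10.0
    irrigation_beta_a: float = 0.6
    irrigation_beta_b: float = 2.4

    # --- weather predictors per county-year (raw scales) ---
    gdd_mean: float = 1800.0
    gdd_temp_slope: float = 60.0  # degree-days per degC of county mean temp
    gdd_year_sd: float = 150.0
    edd_log_mean: float = 4.1  # log degree-days at the reference temperature
    edd_temp_loading: float = 0.12  # per degC on the log scale
    edd_log_sd: float = 0.5
    cdi_mean: float = 0.35
    cdi_precip_slope: float = -2.0e-4  # per mm of annual precip
    cdi_sd: float = 0.12
    temp_ref: float = 15.0
    precip_ref: float = 900.0

    # --- hierarchical truth (standardized covariates & predictors) ---
    base_log_yield: dict[str, float] = field(default_factory=_default_base_log_yield)
    a_trend: float = 0.012
    a_cdi: float = -0.08
    a_gdd: float = 0.05
    a_edd: float = -0.10
    # covariate loadings, rows (intercept, t, cdi, gdd, edd) x 6 covariates
    # (mean_temp, isothermality, temp_seasonality, annual_precip,
    #  precip_seasonality, irrigation fraction)
    loadings: tuple[tuple[float, ...], ...] = (
        (0.10, 0.00, -0.05, 0.08, -0.02, 0.05),
        (0.002, 0.0, 0.0, 0.0, 0.0, 0.001),
        (-0.02, 0.0, 0.0, 0.03, 0.0, 0.04),
        (0.02, 0.01, 0.0, 0.0, 0.0, 0.0),
        (0.04, 0.0, -0.01, 0.01, 0.0, 0.03),
    )
    sigma_alpha: float = 0.12
    sigma_beta: tuple[float, ...] = (0.004, 0.02, 0.02, 0.03)
    sigma: float = 0.10
    heteroscedastic: bool = False  # county-specific residual SDs
    sigma_log_sd: float = 0.3  # spread of log sigma_i when heteroscedastic
    # extra idiosyncratic county-coefficient noise in misspecified mode
    misspec_alpha_sd: float = 0.12
    misspec_beta_sd: tuple[float, ...] = (0.008, 0.04, 0.04, 0.06)
    misspec_df: float = 3.0  # Student-t degrees of freedom

    # --- missingness ---
    unsuitable_quantile: float = 0.2
    dropout_rate: float = 0.03

    # --- economics ---
    prices: dict[str, float] = field(default_factory=_default_prices)
    costs: dict[str, float] = field(default_factory=_default_costs)
    price_cv: float = 0.05
    cost_cv: float = 0.10
    # cultivation cost scales with local expected yield (better land costs
    # more to farm); 0.5 means cost ~ sqrt of relative yield
    cost_yield_elasticity: float = 0.5
    mismatch_fraction: float = 0.4
    county_land_log_mean: float = np.log(30000.0)  # acres
    county_land_log_sd: float = 0.5
    observed_share_low: float = 0.55
    observed_share_high: float = 0.80

    # --- scenarios ---
    scenario_heterogeneity_sd: float = 0.0

    def hyper_for(self, crop: str) -> "CropHyper":
        return CropHyper(
            crop=crop,
            a=np.array(
                [self.base_log_yield[crop], self.a_trend, self.a_cdi, self.a_gdd, self.a_edd]
            ),
            loadings=np.asarray(self.loadings, dtype=float),
            sigma_alpha=self.sigma_alpha,
            sigma_beta=np.asarray(self.sigma_beta, dtype=float),
            sigma=self.sigma,
            sigma_log_sd=self.sigma_log_sd if self.heteroscedastic else 0.0,
        )


@dataclass
class CropHyper:
    """Hyper-level truth for one crop: intercepts, loadings, group SDs."""

    crop: str
    a: np.ndarray  # (5,) expected (intercept, t, cdi, gdd, edd) at average covariates
    loadings: np.ndarray  # (5, 6) covariate loadings on standardized covariates
    sigma_alpha: float
    sigma_beta: np.ndarray  # (4,)
    sigma: float
    sigma_log_sd: float = 0.0


@dataclass
class CropTruth:
    """County-level truth for one crop: the hyper level plus realized effects."""

    hyper: CropHyper
    county_ids: np.ndarray
    alpha: np.ndarray  # (n_counties,)
    beta: np.ndarray  # (n_counties, 4)
    deviations: np.ndarray  # (n_counties, 5) realized departures from covariate means
    sigma_i: np.ndarray  # (n_counties,) residual SD per county

    def linear_predictor(self, county_idx: np.ndarray, x: np.ndarray) -> np.ndarray:
        """alpha_i + beta_i . x for rows indexed into this truth's county order."""
        return self.alpha[county_idx] + np.einsum("ij,ij->i", self.beta[county_idx], x)


@dataclass
class TrueParameters:
    """Full generative truth: per-crop county effects plus the covariate scaler."""

    crops: dict[str, CropTruth]
    scaler: CovariateScaler
    mode: str = "faithful"


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *salt]))


# ---------------------------------------------------------------------------
# counties
# ---------------------------------------------------------------------------


def generate_counties(
    n_counties: int, seed: int, config: GeneratorConfig | None = None
) -> pd.DataFrame:
    """Draw a covariate table for ``n_counties`` synthetic counties.

    Mean temperature and annual precipitation are jointly normal with the
    configured correlation; the remaining climate covariates are
    independent normals clipped to physically sensible ranges; irrigation
    fractions are Beta-distributed per crop (most counties lightly
    irrigated, a right tail of heavily irrigated ones).
    """
    if n_counties < 2:
        raise ValueError("need at least 2 counties")
    cfg = config or GeneratorConfig()
    rng = _rng(seed, 1)
    rho = cfg.temp_precip_corr
    cov = np.array(
        [
            [cfg.mean_temp_sd**2, rho * cfg.mean_temp_sd * cfg.annual_precip_sd],
            [rho * cfg.mean_temp_sd * cfg.annual_precip_sd, cfg.annual_precip_sd**2],
        ]
    )
    tp = rng.multivariate_normal([cfg.mean_temp_mean, cfg.annual_precip_mean], cov, size=n_counties)
    df = pd.DataFrame(
        {
            "county_id": [f"C{i:05d}" for i in range(n_counties)],
            "mean_temp": np.clip(tp[:, 0], 2.0, 28.0),
            "isothermality": np.clip(
                rng.normal(cfg.isothermality_mean, cfg.isothermality_sd, n_counties), 0.2, 0.7
            ),
            "temp_seasonality": np.clip(
                rng.normal(cfg.temp_seasonality_mean, cfg.temp_seasonality_sd, n_counties), 1.0, None
            ),
            "annual_precip": np.clip(tp[:, 1], 100.0, None),
            "precip_seasonality": np.clip(
                rng.normal(cfg.precip_seasonality_mean, cfg.precip_seasonality_sd, n_counties),
                5.0,
                None,
            ),
        }
    )
    for crop in cfg.crops:
        df[f"irrigation_{crop}"] = rng.beta(cfg.irrigation_beta_a, cfg.irrigation_beta_b, n_counties)
    return df


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------


def generate_true_params(
    hyper: Mapping[str, CropHyper] | None,
    covariates: pd.DataFrame,
    seed: int,
    config: GeneratorConfig | None = None,
) -> TrueParameters:
    """Realize county intercepts and coefficients from the covariate model.

    ``hyper`` may be None, in which case the config defaults define the
    hyper level for every crop in the config. In misspecified mode an
    extra Student-t deviation is added to each county coefficient.
    """
    cfg = config or GeneratorConfig()
    if hyper is None:
        hyper = {crop: cfg.hyper_for(crop) for crop in cfg.crops}
    scaler = CovariateScaler.fit(covariates, list(hyper))
    rng = _rng(seed, 2)
    county_ids = covariates["county_id"].to_numpy()
    n = len(county_ids)
    crops: dict[str, CropTruth] = {}
    for crop, h in hyper.items():
        if h.loadings.shape != (5, len(COVARIATE_NAMES) + 1):
            raise ValueError(
                f"{crop}: loadings must be (5, {len(COVARIATE_NAMES) + 1}), got {h.loadings.shape}"
            )
        Wz = scaler.transform(covariates, crop)  # (n, 6)
        means = h.a[None, :] + Wz @ h.loadings.T  # (n, 5)
        sds = np.concatenate([[h.sigma_alpha], h.sigma_beta])
        dev = rng.standard_normal((n, 5)) * sds[None, :]
        if cfg.mode == "misspecified":
            extra = np.concatenate([[cfg.misspec_alpha_sd], np.asarray(cfg.misspec_beta_sd)])
            dev = dev + rng.standard_t(cfg.misspec_df, size=(n, 5)) * extra[None, :]
        theta = means + dev
        if h.sigma_log_sd > 0:
            sigma_i = np.exp(np.log(h.sigma) + h.sigma_log_sd * rng.standard_normal(n))
        else:
            sigma_i = np.full(n, h.sigma)
        crops[crop] = CropTruth(
            hyper=h,
            county_ids=county_ids.copy(),
            alpha=theta[:, 0],
            beta=theta[:, 1:],
            deviations=dev,
            sigma_i=sigma_i,
        )
    return TrueParameters(crops=crops, scaler=scaler, mode=cfg.mode)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


@dataclass
class PanelResult:
    """A generated panel plus the side information downstream stages need.

    ``panel`` holds only observed county-year-crop rows (standardized
    predictors, log yields); ``climatology`` holds mean standardized
    predictors for every county x crop cell, including cells never
    observed — exactly what yield prediction in new locations needs;
    ``grown`` records which county-crop cells are cultivated at baseline.
    """

    panel: pd.DataFrame
    climatology: pd.DataFrame
    scalings: dict
    grown: pd.DataFrame  # columns county_id, crop, grown (bool)


def generate_panel(
    params: TrueParameters,
    covariates: pd.DataFrame,
    n_years: int,
    crops: Sequence[str] | None = None,
    seed: int = 0,
    config: GeneratorConfig | None = None,
) -> PanelResult:
    """Draw predictors and log-yields for a county x year x crop panel.

    Weather predictors are drawn per county-year with the configured
    dependence on county climate (degree-day exposure rises with county
    mean temperature; the deficit index falls with precipitation). Crops
    are missing from counties in the bottom suitability quantile of the
    covariate-implied intercept, plus random county-year dropout; each
    county keeps at least its most suitable crop.
    """
    cfg = config or GeneratorConfig()
    if n_years < 2:
        raise ValueError("need at least 2 years")
    crops = tuple(crops) if crops is not None else tuple(params.crops)
    unknown = set(crops) - set(params.crops)
    if unknown:
        raise ValueError(f"crops without truth: {sorted(unknown)}")
    rng = _rng(seed, 3)
    county_ids = covariates["county_id"].to_numpy()
    n_c = len(county_ids)
    years = np.arange(cfg.base_year, cfg.base_year + n_years)

    # suitability: covariate-implied mean intercept per crop
    suit = {}
    for crop in crops:
        t = params.crops[crop]
        Wz = params.scaler.transform(covariates, crop)
        suit[crop] = t.hyper.a[0] + Wz @ t.hyper.loadings[0]
    suit_df = pd.DataFrame(suit, index=county_ids)
    grown = suit_df.ge(suit_df.quantile(cfg.unsuitable_quantile), axis=1)
    none_grown = ~grown.any(axis=1)
    if none_grown.any():
        best = suit_df.loc[none_grown].idxmax(axis=1)
        for cid, crop in best.items():
            grown.loc[cid, crop] = True

    mt = covariates["mean_temp"].to_numpy()
    ap = covariates["annual_precip"].to_numpy()
    frames = []
    for crop in crops:
        gmask = grown[crop].to_numpy()
        idx_c = np.repeat(np.arange(n_c), n_years)
        yy = np.tile(years, n_c)
        gdd = (
            cfg.gdd_mean
            + cfg.gdd_temp_slope * (mt[idx_c] - cfg.temp_ref)
            + rng.normal(0.0, cfg.gdd_year_sd, idx_c.size)
        )
        edd = np.exp(
            cfg.edd_log_mean
            + cfg.edd_temp_loading * (mt[idx_c] - cfg.temp_ref)
            + rng.normal(0.0, cfg.edd_log_sd, idx_c.size)
        )
        cdi = np.clip(
            cfg.cdi_mean
            + cfg.cdi_precip_slope * (ap[idx_c] - cfg.precip_ref)
            + rng.normal(0.0, cfg.cdi_sd, idx_c.size),
            0.0,
            1.0,
        )
        keep = gmask[idx_c] & (rng.random(idx_c.size) >= cfg.dropout_rate)
        frames.append(
            pd.DataFrame(
                {
                    "county_id": county_ids[idx_c],
                    "year": yy,
                    "crop": crop,
                    "cdi": cdi,
                    "gdd": np.clip(gdd, 0.0, None),
                    "edd": edd,
                    "_keep": keep,
                    "_county_idx": idx_c,
                }
            )
        )
    raw = pd.concat(frames, ignore_index=True)
    raw["log_yield"] = np.nan

    from .predictors import standardize_panel

    kept = raw.loc[raw["_keep"]].reset_index(drop=True)
    std_all, scalings = standardize_panel(
        raw.drop(columns=["_keep"]), base_year=cfg.base_year
    )
    std_all["_keep"] = raw["_keep"].to_numpy()
    panel = std_all.loc[std_all["_keep"]].drop(columns=["_keep"]).reset_index(drop=True)
    del kept

    # log-yields from the hierarchical truth, on the standardized scale
    for crop in crops:
        t = params.crops[crop]
        m = panel["crop"] == crop
        idx = panel.loc[m, "_county_idx"].to_numpy()
        x = panel.loc[m, ["t", "cdi", "gdd", "edd"]].to_numpy()
        mu = t.linear_predictor(idx, x)
        panel.loc[m, "log_yield"] = mu + t.sigma_i[idx] * rng.standard_normal(m.sum())
    panel = panel.drop(columns=["_county_idx"])

    clim = (
        std_all.drop(columns=["_keep", "log_yield", "_county_idx"])
        .groupby(["county_id", "crop"], as_index=False)[["t", "cdi", "gdd", "edd"]]
        .mean()
    )
    grown_long = grown.rename_axis("county_id").reset_index().melt(
        id_vars="county_id", var_name="crop", value_name="grown"
    )
    return PanelResult(panel=panel, climatology=clim, scalings=scalings, grown=grown_long)


# ---------------------------------------------------------------------------
# economics
# ---------------------------------------------------------------------------


def expected_baseline_yields(params: TrueParameters, climatology: pd.DataFrame) -> pd.DataFrame:
    """True expected yield (units/acre) per county x crop at baseline climatology."""
    out = climatology.copy()
    mu = np.empty(len(out))
    for crop, grp in out.groupby("crop"):
        t = params.crops[crop]
        order = {cid: i for i, cid in enumerate(t.county_ids)}
        idx = grp["county_id"].map(order).to_numpy()
        x = grp[["t", "cdi", "gdd", "edd"]].to_numpy()
        mu[grp.index] = t.linear_predictor(idx, x)
    out["yield"] = np.exp(mu)
    return out[["county_id", "crop", "yield"]]


def generate_economics(
    panel_result: PanelResult,
    params: TrueParameters,
    seed: int,
    config: GeneratorConfig | None = None,
) -> pd.DataFrame:
    """Prices, cultivation costs, baseline areas and the designated observed crop.

    The table deliberately leaves a configurable fraction of counties with
    an observed crop that is *not* the per-acre-profit argmax (the
    designated crop is the runner-up among locally grown crops there), so
    the hidden-cost calibration step has real work to do.
    """
    cfg = config or GeneratorConfig()
    rng = _rng(seed, 4)
    yields = expected_baseline_yields(params, panel_result.climatology)
    econ = yields.copy()
    econ["price"] = econ["crop"].map(cfg.prices) * rng.lognormal(0.0, cfg.price_cv, len(econ))
    rel_yield = econ["yield"] / np.exp(econ["crop"].map(cfg.base_log_yield))
    econ["cost"] = (
        econ["crop"].map(cfg.costs)
        * rng.lognormal(0.0, cfg.cost_cv, len(econ))
        * rel_yield**cfg.cost_yield_elasticity
    )
    econ["profit"] = econ["price"] * econ["yield"] - econ["cost"]
    grown = panel_result.grown.set_index(["county_id", "crop"])["grown"]
    econ["grown"] = econ.set_index(["county_id", "crop"]).index.map(grown).fillna(False).astype(bool)

    county_ids = econ["county_id"].unique()
    observed: dict[str, str] = {}
    flip = rng.random(len(county_ids)) < cfg.mismatch_fraction
    for j, cid in enumerate(county_ids):
        sub = econ[(econ["county_id"] == cid) & econ["grown"]].sort_values(
            "profit", ascending=False
        )
        # mismatch is only designated where the runner-up is itself viable:
        # nobody is observed planting a money-losing crop at scale
        if len(sub) >= 2 and flip[j] and sub.iloc[1]["profit"] > 0:
            observed[cid] = sub.iloc[1]["crop"]
        else:
            observed[cid] = sub.iloc[0]["crop"]
    econ["observed_crop"] = econ["county_id"].map(observed)

    land = np.exp(rng.normal(cfg.county_land_log_mean, cfg.county_land_log_sd, len(county_ids)))
    land_map = dict(zip(county_ids, land))
    areas = np.zeros(len(econ))
    for cid in county_ids:
        rows = econ.index[econ["county_id"] == cid]
        grown_rows = [r for r in rows if econ.at[r, "grown"]]
        obs = observed[cid]
        L = land_map[cid]
        share = rng.uniform(cfg.observed_share_low, cfg.observed_share_high)
        others = [r for r in grown_rows if econ.at[r, "crop"] != obs]
        if others:
            w = rng.dirichlet(np.ones(len(others)))
            for r, wi in zip(others, w):
                areas[r] = (1.0 - share) * L * wi
        else:
            share = 1.0
        obs_row = [r for r in grown_rows if econ.at[r, "crop"] == obs][0]
        areas[obs_row] = share * L
    econ["baseline_area"] = areas
    return econ.drop(columns=["profit", "grown"])[
        ["county_id", "crop", "price", "cost", "baseline_area", "observed_crop", "yield"]
    ].rename(columns={"yield": "true_yield"})


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------


@dataclass
class ClimateScenario:
    """Standardized predictor values per county x crop for one period."""

    label: str
    predictors: pd.DataFrame  # county_id, crop, t, cdi, gdd, edd


def generate_scenario(
    climatology: pd.DataFrame,
    warming: Mapping[str, Mapping[str, float]],
    label: str,
    seed: int = 0,
    heterogeneity_sd: float = 0.0,
) -> ClimateScenario:
    """Shift baseline climatology by per-crop amounts in SD units.

    ``warming`` maps crop -> {predictor: shift}; unknown crops or
    predictors raise. ``heterogeneity_sd`` adds seeded county-specific
    normal scatter around each specified mean shift. The trend predictor
    is left at its baseline value (the analysis isolates climate effects
    from technology-trend extrapolation).
    """
    known_crops = set(climatology["crop"].unique())
    rng = _rng(seed, 5)
    preds = climatology.copy()
    for crop, shifts in warming.items():
        if crop not in known_crops:
            raise ValueError(f"unknown crop in warming spec: {crop}")
        m = preds["crop"] == crop
        for name, delta in shifts.items():
            if name not in ("cdi", "gdd", "edd"):
                raise ValueError(f"unknown predictor in warming spec: {name}")
            noise = heterogeneity_sd * rng.standard_normal(int(m.sum()))
            preds.loc[m, name] = preds.loc[m, name] + delta + noise
    return ClimateScenario(label=label, predictors=preds)


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------


@dataclass
class SyntheticData:
    covariates: pd.DataFrame
    truth: TrueParameters
    panel_result: PanelResult
    economics: pd.DataFrame
    config: GeneratorConfig


def simulate(
    n_counties: int,
    n_years: int,
    seed: int,
    config: GeneratorConfig | None = None,
    crops: Sequence[str] | None = None,
) -> SyntheticData:
    """Generate a complete synthetic study: counties, truth, panel, economics."""
    cfg = config or GeneratorConfig()
    if crops is not None:
        cfg = replace(cfg, crops=tuple(crops))
    cov = generate_counties(n_counties, seed, cfg)
    truth = generate_true_params(None, cov, seed, cfg)
    pr = generate_panel(truth, cov, n_years, cfg.crops, seed, cfg)
    econ = generate_economics(pr, truth, seed, cfg)
    return SyntheticData(covariates=cov, truth=truth, panel_result=pr, economics=econ, config=cfg)
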