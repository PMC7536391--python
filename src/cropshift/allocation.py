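"""Profit-maximizing reallocation of crop land as a linear program.

For each posterior draw of expected yields Yhat_ic, the optimizer chooses
acreage A_ic >= 0 to maximize

    sum_ic (p_ic Yhat_ic - o_ic) A_ic  [ - s * sum_ic max(0, A_ic - Abar_ic) ]

subject to two caps: no county farms more land than its current total
(sum_c A_ic <= sum_c Abar_ic), and no crop exceeds its current national
total (sum_i A_ic <= sum_i Abar_ic). The crop-total cap is the device
that avoids modelling price responses. The optional switching cost s
(USD/acre) is charged on acres of a crop beyond its baseline area in the
county, linearized with slack variables; land may be left fallow where
no crop is profitable. The constraint matrix is a transportation-type
row/column incidence, so with integer supplies and caps the LP optimum
is attained at an integer vertex.

Before optimizing, cultivation costs are calibrated so that the
designated observed crop is the per-acre-profit argmax in every county
("hidden costs": unmodelled local factors that keep the observed crop in
place). The Monte Carlo driver re-solves the LP for each posterior draw
and period and aggregates profit, switching and production outcomes with
equal-tailed 95% credible intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .covariates import CovariateScaler
from .hier import PosteriorDraws, predict_coefficients

__all__ = [
    "ProfitSurface",
    "Allocation",
    "OutcomeSummary",
    "calibrate_hidden_costs",
    "optimize_allocation",
    "apply_irrigation_adjustment",
    "monte_carlo_optimize",
    "summarize_switching",
    "sweep_switching_costs",
]

FALLOW = "fallow"


@dataclass
class ProfitSurface:
    """Expected per-acre economics on a county x crop grid for one draw/period."""

    counties: np.ndarray  # (n_i,)
    crops: np.ndarray  # (n_c,)
    yields: np.ndarray  # (n_i, n_c) yield units / acre
    prices: np.ndarray  # (n_i, n_c) USD / yield unit
    costs: np.ndarray  # (n_i, n_c) USD / acre
    period: str = "baseline"
    draw: int = -1

    @property
    def profit(self) -> np.ndarray:
        """Per-acre profit pi_ic = p_ic * Yhat_ic - o_ic (USD/acre)."""
        return self.prices * self.yields - self.costs


@dataclass
class Allocation:
    """LP solution: acreage per county x crop plus solver audits."""

    counties: np.ndarray
    crops: np.ndarray
    areas: np.ndarray  # (n_i, n_c) acres
    objective: float  # USD, net of any switching penalty
    gross_profit: float  # USD, sum pi * A
    reallocated_acres: float  # sum max(0, A - Abar)
    duality_gap: float  # |primal - dual| / max(1, |primal|)
    switching_cost: float = 0.0

    def to_frame(self, period: str = "baseline") -> pd.DataFrame:
        n_i, n_c = self.areas.shape
        return pd.DataFrame(
            {
                "county_id": np.repeat(self.counties, n_c),
                "crop": np.tile(self.crops, n_i),
                "period": period,
                "acres": self.areas.reshape(-1),
            }
        )


def _econ_matrices(econ: pd.DataFrame, value_cols: Sequence[str]):
    counties = np.sort(econ["county_id"].unique())
    crops = np.sort(econ["crop"].unique())
    mats = []
    for col in value_cols:
        piv = econ.pivot(index="county_id", columns="crop", values=col).loc[counties, crops]
        if piv.isna().any().any():
            raise ValueError(f"economics table missing {col} for some county x crop cells")
        mats.append(piv.to_numpy(dtype=float))
    return counties, crops, mats


def calibrate_hidden_costs(
    econ: pd.DataFrame,
    baseline_yields: pd.DataFrame,
    epsilon: float = 1.0,
    mode: str = "raise_competitors",
) -> pd.DataFrame:
    """Adjust costs so each county's observed crop is the optimizer's choice.

    ``baseline_yields`` supplies expected yields (county_id, crop, yield)
    at baseline climate. "Optimal" means the allocation LP would plant
    the observed crop: it must beat every competitor by ``epsilon``
    USD/acre *and* beat leaving the land fallow. So (1) if the observed
    crop's own profit is below ``epsilon`` its cost is lowered to reach
    that margin (hidden support absorbed into the cost figure), then
    (2) where a competitor's profit reaches the observed crop's minus
    ``epsilon``, either the competitor's cost is raised (default) or the
    observed crop's cost lowered, by the minimal amount. Counties
    already consistent are untouched.
    """
    if mode not in ("raise_competitors", "lower_observed"):
        raise ValueError("mode must be 'raise_competitors' or 'lower_observed'")
    out = econ.copy()
    y = baseline_yields.set_index(["county_id", "crop"])["yield"]
    key = out.set_index(["county_id", "crop"]).index
    if not key.isin(y.index).all():
        missing = key[~key.isin(y.index)][:5].tolist()
        raise ValueError(f"baseline yields missing for cells: {missing}")
    out["_yield"] = y.loc[key].to_numpy()
    out["_profit"] = out["price"] * out["_yield"] - out["cost"]
    for cid, grp in out.groupby("county_id", sort=False):
        obs = grp["observed_crop"].iloc[0]
        obs_rows = grp.index[grp["crop"] == obs]
        if len(obs_rows) == 0:
            raise ValueError(f"county {cid}: observed crop {obs!r} absent from economics table")
        pi_obs = float(grp.loc[obs_rows[0], "_profit"])
        if pi_obs < epsilon:  # must beat the fallow option too
            out.loc[obs_rows[0], "cost"] = out.loc[obs_rows[0], "cost"] - (epsilon - pi_obs)
            pi_obs = epsilon
        others = grp.index[grp["crop"] != obs]
        excess = grp.loc[others, "_profit"] - (pi_obs - epsilon)
        if mode == "raise_competitors":
            bump = excess.clip(lower=0.0)
            out.loc[others, "cost"] = out.loc[others, "cost"] + bump
        else:
            worst = float(excess.max()) if len(others) else 0.0
            if worst > 0:
                out.loc[obs_rows[0], "cost"] = out.loc[obs_rows[0], "cost"] - worst
    return out.drop(columns=["_yield", "_profit"])


def optimize_allocation(
    surface: ProfitSurface,
    baseline_areas: np.ndarray,
    switching_cost: float = 0.0,
    crop_caps: np.ndarray | None = None,
) -> Allocation:
    """Solve the land-reallocation LP for one profit surface.

    ``baseline_areas`` is (n_i, n_c) current acres; county land totals
    are its row sums and, unless ``crop_caps`` overrides them, crop caps
    are its column sums. With ``switching_cost`` s > 0 the objective
    subtracts s per acre of a crop beyond its baseline area in a county.
    """
    if switching_cost < 0:
        raise ValueError("switching_cost must be >= 0")
    pi = surface.profit
    n_i, n_c = pi.shape
    if baseline_areas.shape != pi.shape:
        raise ValueError("baseline_areas shape mismatch with surface")
    land = baseline_areas.sum(axis=1)
    caps = baseline_areas.sum(axis=0) if crop_caps is None else np.asarray(crop_caps, float)
    nv = n_i * n_c
    row_i = np.repeat(np.arange(n_i), n_c)
    col_c = np.tile(np.arange(n_c), n_i)
    county_con = sparse.csr_matrix((np.ones(nv), (row_i, np.arange(nv))), shape=(n_i, nv))
    crop_con = sparse.csr_matrix((np.ones(nv), (col_c, np.arange(nv))), shape=(n_c, nv))
    if switching_cost > 0:
        # variables [A, u], u_ic >= A_ic - Abar_ic
        A_ub = sparse.vstack(
            [
                sparse.hstack([county_con, sparse.csr_matrix((n_i, nv))]),
                sparse.hstack([crop_con, sparse.csr_matrix((n_c, nv))]),
                sparse.hstack([sparse.eye(nv), -sparse.eye(nv)]),
            ],
            format="csr",
        )
        b_ub = np.concatenate([land, caps, baseline_areas.reshape(-1)])
        c = np.concatenate([-pi.reshape(-1), np.full(nv, switching_cost)])
    else:
        A_ub = sparse.vstack([county_con, crop_con], format="csr")
        b_ub = np.concatenate([land, caps])
        c = -pi.reshape(-1)
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"LP failed ({res.status}): {res.message}")
    x = res.x[:nv]
    areas = x.reshape(n_i, n_c)
    # duality certificate: for min c'x s.t. Ax<=b, x>=0 the dual optimum is b'y
    # with the (non-positive) constraint marginals y
    dual = float(b_ub @ res.ineqlin.marginals)
    gap = abs(res.fun - dual) / max(1.0, abs(res.fun))
    realloc = float(np.maximum(areas - baseline_areas, 0.0).sum())
    gross = float((pi * areas).sum())
    return Allocation(
        counties=surface.counties,
        crops=surface.crops,
        areas=areas,
        objective=-float(res.fun),
        gross_profit=gross,
        reallocated_acres=realloc,
        duality_gap=gap,
        switching_cost=switching_cost,
    )


def audit_allocation(alloc: Allocation, baseline_areas: np.ndarray, tol: float = 1e-6) -> None:
    """Exact post-hoc constraint audit; raises on violation beyond tolerance."""
    scale = max(1.0, float(baseline_areas.max()))
    if (alloc.areas < -tol * scale).any():
        raise AssertionError("negative acreage in allocation")
    row_slack = alloc.areas.sum(axis=1) - baseline_areas.sum(axis=1)
    col_slack = alloc.areas.sum(axis=0) - baseline_areas.sum(axis=0)
    if (row_slack > tol * scale).any():
        raise AssertionError("county land constraint violated")
    if (col_slack > tol * scale).any():
        raise AssertionError("crop total constraint violated")


def apply_irrigation_adjustment(
    surface: ProfitSurface,
    coef_models: Mapping[str, tuple[np.ndarray, CovariateScaler]],
    predictors: pd.DataFrame,
    source_fracs: pd.DataFrame,
    dest_fracs: pd.DataFrame,
) -> ProfitSurface:
    """Re-evaluate yields at the destination county's irrigation fraction.

    The hierarchical model carries irrigation as a covariate, so a crop
    entering a county inherits that county's irrigation capacity through
    the covariate pathway: each mean coefficient shifts by its irrigation
    loading times the standardized change in fraction. ``coef_models``
    maps crop -> (gamma (5,7) hyper matrix, covariate scaler);
    ``predictors`` holds standardized (county_id, crop, t, cdi, gdd, edd);
    the fraction frames are county x crop (wide, indexed by county_id).
    """
    new_yields = surface.yields.copy()
    pred = predictors.set_index(["county_id", "crop"])
    for c, crop in enumerate(surface.crops):
        if crop not in coef_models:
            raise ValueError(f"no coefficient model for crop {crop!r}")
        gamma, scaler = coef_models[crop]
        irr_sd = scaler.sds[crop][-1]
        b_irr = gamma[:, -1]  # irrigation loadings of (alpha, beta_1..4)
        for i, cid in enumerate(surface.counties):
            try:
                src = float(source_fracs.loc[cid, crop])
                dst = float(dest_fracs.loc[cid, crop])
            except KeyError as err:
                raise ValueError(f"missing irrigation fraction for ({cid}, {crop})") from err
            if not (0.0 <= dst <= 1.0) or not (0.0 <= src <= 1.0):
                raise ValueError("irrigation fractions must lie in [0, 1]")
            dz = (dst - src) / irr_sd
            x = pred.loc[(cid, crop), ["t", "cdi", "gdd", "edd"]].to_numpy(dtype=float)
            dmu = dz * (b_irr[0] + float(b_irr[1:] @ x))
            new_yields[i, c] *= np.exp(dmu)
    out = ProfitSurface(
        counties=surface.counties,
        crops=surface.crops,
        yields=new_yields,
        prices=surface.prices,
        costs=surface.costs,
        period=surface.period,
        draw=surface.draw,
    )
    return out


# ---------------------------------------------------------------------------
# switching summaries
# ---------------------------------------------------------------------------


def _dominant(areas: np.ndarray, crops: np.ndarray, baseline_dominant: np.ndarray) -> np.ndarray:
    """Largest-area crop per county; ties resolved toward the baseline
    dominant crop; all-fallow counties labelled 'fallow'."""
    n_i = areas.shape[0]
    out = np.empty(n_i, dtype=object)
    row_max = areas.max(axis=1)
    for i in range(n_i):
        if row_max[i] <= 0:
            out[i] = FALLOW
            continue
        tied = np.where(np.isclose(areas[i], row_max[i], rtol=1e-9, atol=1e-9))[0]
        names = crops[tied]
        out[i] = baseline_dominant[i] if baseline_dominant[i] in names else names[0]
    return out


def summarize_switching(
    areas: np.ndarray,
    baseline_areas: np.ndarray,
    crops: np.ndarray,
) -> dict:
    """Switching and land-flow statistics for one allocation.

    A county "switches" when its largest-area crop differs from the
    baseline dominant crop; corn<->soy exchanges are excluded in the
    second statistic (the two are commonly grown in rotation, so such
    swaps are not treated as meaningful switches). The flow matrix keeps
    acres on their baseline crop up to min(baseline, new) and attributes
    only each county's surplus acres to its deficit crops (proportional
    to deficits) or to fallow (rows: baseline crop; columns: crops plus
    fallow) — so an unchanged allocation yields a diagonal matrix.
    """
    crops = np.asarray(crops)
    dom_base = _dominant(baseline_areas, crops, np.array([None] * len(baseline_areas)))
    dom_opt = _dominant(areas, crops, dom_base)
    switched = dom_opt != dom_base
    cornsoy = {"corn", "soybeans"}
    excl = np.array(
        [
            s and not ({b, o} <= cornsoy)
            for s, b, o in zip(switched, dom_base, dom_opt)
        ]
    )
    land = baseline_areas.sum(axis=1)
    used = areas.sum(axis=1)
    fallow = np.maximum(land - used, 0.0)
    flow = pd.DataFrame(0.0, index=list(crops), columns=[*crops, FALLOW])
    stay = np.minimum(baseline_areas, areas)
    surplus = baseline_areas - stay  # (n_i, n_c)
    deficit = areas - stay
    total_deficit = deficit.sum(axis=1) + fallow
    for c, crop in enumerate(crops):
        flow.loc[crop, crop] += float(stay[:, c].sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total_deficit[:, None] > 0, deficit / np.where(total_deficit[:, None] > 0, total_deficit[:, None], 1.0), 0.0)
        frac_fallow = np.where(total_deficit > 0, fallow / np.where(total_deficit > 0, total_deficit, 1.0), 0.0)
    for b, bcrop in enumerate(crops):
        s = surplus[:, b]
        flow.loc[bcrop, list(crops)] += (s[:, None] * frac).sum(axis=0)
        flow.loc[bcrop, FALLOW] += float((s * frac_fallow).sum())
    total_land = float(land.sum())
    return {
        "pct_switched": 100.0 * float(np.mean(switched)),
        "pct_switched_excl_corn_soy": 100.0 * float(np.mean(excl)),
        "fallow_fraction": float(fallow.sum() / total_land) if total_land > 0 else 0.0,
        "flow_matrix": flow,
        "dominant_baseline": dom_base,
        "dominant_optimized": dom_opt,
    }


# ---------------------------------------------------------------------------
# posterior-draw Monte Carlo
# ---------------------------------------------------------------------------


@dataclass
class OutcomeSummary:
    """Per-draw outcomes and their aggregation with 95% credible intervals."""

    per_draw: pd.DataFrame  # period, draw, profit_opt, profit_sq, pct_switched, ...
    summary: pd.DataFrame  # period x statistic with mean/lo/hi
    flow_matrices: dict = field(default_factory=dict)  # period -> mean flow matrix
    production_change: pd.DataFrame | None = None  # period x crop, % vs status quo


def _ci(values: np.ndarray) -> tuple[float, float]:
    return float(np.quantile(values, 0.025)), float(np.quantile(values, 0.975))


def monte_carlo_optimize(
    draws_by_crop: Mapping[str, PosteriorDraws],
    econ: pd.DataFrame,
    covariates: pd.DataFrame,
    scenarios: Sequence,
    n_draws_used: int = 30,
    seed: int = 0,
    switching_cost: float = 0.0,
    calibrate: bool = True,
    epsilon: float = 1.0,
    calibration_mode: str = "raise_competitors",
) -> tuple[dict, OutcomeSummary]:
    """Re-solve the reallocation LP for each sampled posterior draw and period.

    ``scenarios`` is a sequence of ClimateScenario-like objects (label +
    standardized predictor table); the first is treated as the baseline
    period used for hidden-cost calibration. Yields for every county x
    crop cell — including cells never observed growing the crop — come
    from the covariate model via :func:`predict_coefficients`. Expected
    yield per draw is exp of the mean function (no observation-noise
    resampling: the optimizer targets expected profit).

    Returns (allocations, OutcomeSummary) where ``allocations`` maps
    (period_label, draw_index) -> Allocation.
    """
    counties, crops, (prices, costs, base_areas) = _econ_matrices(
        econ, ["price", "cost", "baseline_area"]
    )
    cov = covariates.set_index("county_id").loc[counties].reset_index()
    preds = {}
    for crop in crops:
        if crop not in draws_by_crop:
            raise ValueError(f"no posterior draws for crop {crop!r}")
        preds[crop] = predict_coefficients(draws_by_crop[crop], cov, seed=seed)
    S = min(p.theta.shape[0] for p in preds.values())
    if n_draws_used > S:
        raise ValueError(f"n_draws_used={n_draws_used} exceeds available draws ({S})")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 19]))
    draw_idx = rng.choice(S, size=n_draws_used, replace=False)

    def yields_for(theta_sel: dict, scenario) -> np.ndarray:
        ptab = scenario.predictors.set_index(["county_id", "crop"])
        Y = np.empty((len(counties), len(crops)))
        for c, crop in enumerate(crops):
            x = ptab.loc[[(cid, crop) for cid in counties], ["t", "cdi", "gdd", "edd"]].to_numpy(
                dtype=float
            )
            th = theta_sel[crop]  # (n_i, 5)
            Y[:, c] = np.exp(th[:, 0] + np.einsum("ij,ij->i", th[:, 1:], x))
        return Y

    baseline = scenarios[0]
    if calibrate:
        theta_mean = {crop: preds[crop].theta.mean(axis=0) for crop in crops}
        Ybase = yields_for(theta_mean, baseline)
        ydf = pd.DataFrame(
            {
                "county_id": np.repeat(counties, len(crops)),
                "crop": np.tile(crops, len(counties)),
                "yield": Ybase.reshape(-1),
            }
        )
        econ = calibrate_hidden_costs(econ, ydf, epsilon=epsilon, mode=calibration_mode)
        counties, crops, (prices, costs, base_areas) = _econ_matrices(
            econ, ["price", "cost", "baseline_area"]
        )

    allocations: dict = {}
    records = []
    flow_acc: dict[str, list[pd.DataFrame]] = {}
    prod_records = []
    for scen in scenarios:
        for d in draw_idx:
            theta_sel = {crop: preds[crop].theta[d] for crop in crops}
            Y = yields_for(theta_sel, scen)
            surf = ProfitSurface(
                counties=counties, crops=crops, yields=Y, prices=prices, costs=costs,
                period=scen.label, draw=int(d),
            )
            alloc = optimize_allocation(surf, base_areas, switching_cost=switching_cost)
            audit_allocation(alloc, base_areas)
            pi = surf.profit
            profit_sq = float((pi * base_areas).sum())
            if alloc.objective < profit_sq - 1e-6 * max(1.0, abs(profit_sq)):
                raise AssertionError(
                    f"optimized profit below status quo for draw {d} period {scen.label}"
                )
            sw = summarize_switching(alloc.areas, base_areas, crops)
            allocations[(scen.label, int(d))] = alloc
            records.append(
                {
                    "period": scen.label,
                    "draw": int(d),
                    "profit_opt": alloc.objective,
                    "profit_gross": alloc.gross_profit,
                    "profit_sq": profit_sq,
                    "pct_switched": sw["pct_switched"],
                    "pct_switched_excl_corn_soy": sw["pct_switched_excl_corn_soy"],
                    "fallow_fraction": sw["fallow_fraction"],
                    "reallocated_acres": alloc.reallocated_acres,
                    "duality_gap": alloc.duality_gap,
                }
            )
            flow_acc.setdefault(scen.label, []).append(sw["flow_matrix"])
            prod_opt = (Y * alloc.areas).sum(axis=0)
            prod_sq = (Y * base_areas).sum(axis=0)
            for c, crop in enumerate(crops):
                prod_records.append(
                    {
                        "period": scen.label,
                        "draw": int(d),
                        "crop": crop,
                        "production_change_pct": 100.0 * (prod_opt[c] / prod_sq[c] - 1.0)
                        if prod_sq[c] > 0
                        else np.nan,
                    }
                )
    per_draw = pd.DataFrame(records)
    stats = ["profit_opt", "profit_sq", "pct_switched", "pct_switched_excl_corn_soy", "fallow_fraction"]
    rows = []
    for period, grp in per_draw.groupby("period", sort=False):
        for stat in stats:
            lo, hi = _ci(grp[stat].to_numpy())
            rows.append(
                {"period": period, "statistic": stat, "mean": float(grp[stat].mean()), "lo": lo, "hi": hi}
            )
    summary = pd.DataFrame(rows)
    flows = {p: sum(fs) / len(fs) for p, fs in flow_acc.items()}
    prod = (
        pd.DataFrame(prod_records)
        .groupby(["period", "crop"], sort=False)["production_change_pct"]
        .agg(["mean", lambda v: np.quantile(v, 0.025), lambda v: np.quantile(v, 0.975)])
        .rename(columns={"<lambda_0>": "lo", "<lambda_1>": "hi"})
        .reset_index()
    )
    return allocations, OutcomeSummary(
        per_draw=per_draw, summary=summary, flow_matrices=flows, production_change=prod
    )


def sweep_switching_costs(
    surface: ProfitSurface,
    baseline_areas: np.ndarray,
    grid: Sequence[float],
) -> pd.DataFrame:
    """Solve the LP across a grid of switching costs (one profit surface).

    The optimal objective and the reallocated acreage are both
    non-increasing in the cost; at large costs the allocation converges
    to the baseline-feasible status quo (unprofitable acres fallowed).
    """
    rows = []
    for s in grid:
        alloc = optimize_allocation(surface, baseline_areas, switching_cost=float(s))
        rows.append(
            {
                "switching_cost": float(s),
                "objective": alloc.objective,
                "gross_profit": alloc.gross_profit,
                "reallocated_acres": alloc.reallocated_acres,
                "duality_gap": alloc.duality_gap,
            }
        )
    return pd.DataFrame(rows)
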