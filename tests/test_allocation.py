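"""Hidden-cost calibration, the reallocation LP, and outcome summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cropshift import allocation as al
from cropshift import hier, synth


def _surface(pi, counties=None, crops=None):
    """Profit surface with unit yields/prices so profit == -costs offset."""
    pi = np.asarray(pi, dtype=float)
    n_i, n_c = pi.shape
    return al.ProfitSurface(
        counties=np.array(counties or [f"C{i}" for i in range(n_i)]),
        crops=np.array(crops or [f"crop{j}" for j in range(n_c)]),
        yields=np.ones((n_i, n_c)),
        prices=np.ones((n_i, n_c)),
        costs=1.0 - pi,
    )


def brute_force_optimum(pi, base):
    """Independent oracle: exhaustive search over integer allocations."""
    land = base.sum(axis=1).astype(int)
    caps = base.sum(axis=0).astype(int)
    n_i, n_c = pi.shape
    best = 0.0
    cell_ranges = [range(int(min(land[i], caps[j])) + 1) for i in range(n_i) for j in range(n_c)]
    for comb in itertools.product(*cell_ranges):
        A = np.asarray(comb, dtype=float).reshape(n_i, n_c)
        if (A.sum(axis=1) <= land).all() and (A.sum(axis=0) <= caps).all():
            best = max(best, float((pi * A).sum()))
    return best


class TestCalibration:
    def _econ(self):
        return pd.DataFrame(
            {
                "county_id": ["A", "A", "B", "B"],
                "crop": ["corn", "soybeans"] * 2,
                "price": [1.0, 1.0, 1.0, 1.0],
                "cost": [0.0, 0.0, 0.0, 0.0],
                "baseline_area": [80.0, 20.0, 70.0, 30.0],
                "observed_crop": ["corn", "corn", "corn", "corn"],
            }
        )

    def _yields(self, a_corn=100.0, a_soy=120.0, b_corn=100.0, b_soy=50.0):
        return pd.DataFrame(
            {
                "county_id": ["A", "A", "B", "B"],
                "crop": ["corn", "soybeans"] * 2,
                "yield": [a_corn, a_soy, b_corn, b_soy],
            }
        )

    def test_minimal_competitor_markup(self):
        """profits (corn 100, soy 120), observed corn, margin 1 -> soy cost +21."""
        out = al.calibrate_hidden_costs(self._econ(), self._yields(), epsilon=1.0)
        soy_a = out[(out["county_id"] == "A") & (out["crop"] == "soybeans")]["cost"].iloc[0]
        assert soy_a == pytest.approx(21.0)

    def test_consistent_county_untouched(self):
        out = al.calibrate_hidden_costs(self._econ(), self._yields(), epsilon=1.0)
        b = out[out["county_id"] == "B"]
        np.testing.assert_allclose(b["cost"], 0.0, atol=1e-12)

    def test_lower_observed_mode(self):
        out = al.calibrate_hidden_costs(
            self._econ(), self._yields(), epsilon=1.0, mode="lower_observed"
        )
        corn_a = out[(out["county_id"] == "A") & (out["crop"] == "corn")]["cost"].iloc[0]
        assert corn_a == pytest.approx(-21.0)

    def test_argmax_audit_after_calibration(self, multi_world):
        econ = multi_world.economics
        y = econ[["county_id", "crop", "true_yield"]].rename(columns={"true_yield": "yield"})
        out = al.calibrate_hidden_costs(econ, y, epsilon=1.0)
        out = out.merge(y, on=["county_id", "crop"])
        out["profit"] = out["price"] * out["yield"] - out["cost"]
        for cid, grp in out.groupby("county_id"):
            assert grp.loc[grp["profit"].idxmax(), "crop"] == grp["observed_crop"].iloc[0]

    def test_unviable_observed_crop_made_profitable(self):
        """A county whose observed crop loses money gets its cost lowered:
        the optimizer must prefer the observed crop to fallowing."""
        econ = self._econ()
        # county B: corn profit 100-110 = -10, soy profit 50-100 = -50
        econ.loc[(econ["county_id"] == "B") & (econ["crop"] == "corn"), "cost"] = 110.0
        econ.loc[(econ["county_id"] == "B") & (econ["crop"] == "soybeans"), "cost"] = 100.0
        out = al.calibrate_hidden_costs(econ, self._yields(), epsilon=1.0)
        corn_b = out[(out["county_id"] == "B") & (out["crop"] == "corn")]["cost"].iloc[0]
        # cost drops by 11 so the observed crop clears fallow by the margin
        assert corn_b == pytest.approx(99.0)

    def test_missing_yield_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            al.calibrate_hidden_costs(self._econ(), self._yields().iloc[:3])


class TestOptimize:
    def test_single_county_all_land_to_best_crop(self):
        surf = _surface([[10.0, 5.0]])
        base = np.array([[50.0, 50.0]])
        a = al.optimize_allocation(surf, base, crop_caps=np.array([100.0, 100.0]))
        np.testing.assert_allclose(a.areas, [[100.0, 0.0]], atol=1e-7)
        assert a.objective == pytest.approx(1000.0)

    def test_all_negative_profits_leave_land_fallow(self):
        surf = _surface([[-3.0, -1.0], [-2.0, -5.0]])
        base = np.full((2, 2), 25.0)
        a = al.optimize_allocation(surf, base)
        np.testing.assert_allclose(a.areas, 0.0, atol=1e-9)
        assert a.objective == pytest.approx(0.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        pi = rng.normal(2, 3, (3, 3))
        base = rng.integers(1, 5, (3, 3)).astype(float)
        a1 = al.optimize_allocation(_surface(pi), base)
        a2 = al.optimize_allocation(_surface(7.0 * pi), base)
        assert a2.objective == pytest.approx(7.0 * a1.objective, rel=1e-9)
        np.testing.assert_allclose(a1.areas, a2.areas, atol=1e-6)

    def test_matches_brute_force_on_integer_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n_i, n_c = rng.integers(1, 4), rng.integers(1, 4)
            base = rng.integers(0, 4, (n_i, n_c)).astype(float)
            pi = rng.integers(-5, 9, (n_i, n_c)).astype(float)
            a = al.optimize_allocation(_surface(pi), base)
            assert a.objective == pytest.approx(brute_force_optimum(pi, base), abs=1e-6)
            assert a.duality_gap <= 1e-8

    def test_negative_switching_cost_rejected(self):
        with pytest.raises(ValueError, match="switching_cost"):
            al.optimize_allocation(_surface([[1.0]]), np.ones((1, 1)), switching_cost=-1)

    def test_audit_catches_violations(self):
        surf = _surface([[5.0, 1.0]])
        base = np.array([[10.0, 10.0]])
        a = al.optimize_allocation(surf, base)
        al.audit_allocation(a, base)
        a.areas[0, 0] = 100.0
        with pytest.raises(AssertionError, match="county land"):
            al.audit_allocation(a, base)


class TestSwitchingCostSweep:
    def test_monotone_and_converges_to_status_quo(self):
        rng = np.random.default_rng(4)
        pi = rng.uniform(5, 60, (6, 3))
        base = rng.integers(10, 100, (6, 3)).astype(float)
        sweep = al.sweep_switching_costs(_surface(pi), base, [0, 10, 50, 200, 10_000])
        assert (np.diff(sweep["objective"]) <= 1e-6).all()
        assert (np.diff(sweep["reallocated_acres"]) <= 1e-6).all()
        assert sweep["reallocated_acres"].iloc[-1] == pytest.approx(0.0, abs=1e-6)
        # with all profits positive the terminal allocation is the status quo
        a = al.optimize_allocation(_surface(pi), base, switching_cost=10_000.0)
        np.testing.assert_allclose(a.areas, base, atol=1e-6)


class TestIrrigationAdjustment:
    def _setup(self, irr_loading):
        gamma = np.zeros((5, 7))
        gamma[:, -1] = irr_loading
        scaler_cov = synth.generate_counties(10, seed=5)
        from cropshift.covariates import CovariateScaler

        scaler = CovariateScaler.fit(scaler_cov, ["corn"])
        surf = _surface([[4.0], [2.0]], counties=["A", "B"], crops=["corn"])
        preds = pd.DataFrame(
            {
                "county_id": ["A", "B"],
                "crop": "corn",
                "t": 0.0,
                "cdi": 0.5,
                "gdd": 1.0,
                "edd": 2.0,
            }
        )
        fr = pd.DataFrame({"corn": [0.2, 0.6]}, index=["A", "B"])
        return gamma, scaler, surf, preds, fr

    def test_equal_fractions_identity(self):
        gamma, scaler, surf, preds, fr = self._setup(irr_loading=0.5)
        out = al.apply_irrigation_adjustment(surf, {"corn": (gamma, scaler)}, preds, fr, fr)
        np.testing.assert_allclose(out.yields, surf.yields, atol=1e-14)

    def test_zero_loading_identity(self):
        gamma, scaler, surf, preds, fr = self._setup(irr_loading=0.0)
        fr2 = fr + 0.3
        out = al.apply_irrigation_adjustment(surf, {"corn": (gamma, scaler)}, preds, fr, fr2)
        np.testing.assert_allclose(out.yields, surf.yields, atol=1e-14)

    def test_matches_manual_propagation(self):
        gamma, scaler, surf, preds, fr = self._setup(irr_loading=0.0)
        gamma[0, -1] = 0.2  # intercept loading
        gamma[4, -1] = -0.1  # EDD-coefficient loading
        dest = fr + 0.25
        out = al.apply_irrigation_adjustment(surf, {"corn": (gamma, scaler)}, preds, fr, dest)
        irr_sd = scaler.sds["corn"][-1]
        dz = 0.25 / irr_sd
        dmu = dz * (0.2 + (-0.1) * 2.0)  # loading on alpha plus loading on beta_edd * edd
        np.testing.assert_allclose(out.yields, surf.yields * np.exp(dmu), rtol=1e-12)

    def test_missing_fraction_rejected(self):
        gamma, scaler, surf, preds, fr = self._setup(0.1)
        with pytest.raises(ValueError, match="missing irrigation"):
            al.apply_irrigation_adjustment(
                surf, {"corn": (gamma, scaler)}, preds, fr.iloc[:1], fr.iloc[:1]
            )


class TestSwitchingSummary:
    CROPS = np.array(["barley", "corn", "soybeans"])

    def test_identity_allocation(self):
        base = np.array([[60.0, 30, 10], [10, 70, 20.0]])
        sw = al.summarize_switching(base, base, self.CROPS)
        assert sw["pct_switched"] == 0.0
        assert sw["fallow_fraction"] == 0.0
        flow = sw["flow_matrix"]
        np.testing.assert_allclose(
            np.diag(flow.loc[self.CROPS, self.CROPS]), base.sum(axis=0), atol=1e-9
        )

    def test_corn_soy_swap_excluded(self):
        base = np.array([[0.0, 80, 20]])
        new = np.array([[0.0, 20, 80]])
        sw = al.summarize_switching(new, base, self.CROPS)
        assert sw["pct_switched"] == 100.0
        assert sw["pct_switched_excl_corn_soy"] == 0.0

    def test_hand_tallied_flows(self):
        base = np.array([[100.0, 0, 0], [0, 50.0, 50.0], [80.0, 20.0, 0], [0, 0, 60.0]])
        new = np.array([[0.0, 100.0, 0], [0, 100.0, 0], [50.0, 0, 0], [0, 0, 60.0]])
        sw = al.summarize_switching(new, base, self.CROPS)
        flow = sw["flow_matrix"]
        # hand tally with the min-stay rule:
        # county 0: barley 100 -> corn 100 (full switch)
        # county 1: corn 50 stays; soy surplus 50 -> corn deficit 50
        # county 2: barley keeps 50, surplus barley 30 and corn 20 -> fallow 50
        # county 3: soy 60 unchanged
        assert flow.loc["barley", "corn"] == pytest.approx(100.0)
        assert flow.loc["barley", "barley"] == pytest.approx(50.0)
        assert flow.loc["barley", al.FALLOW] == pytest.approx(30.0)
        assert flow.loc["corn", "corn"] == pytest.approx(50.0)
        assert flow.loc["corn", al.FALLOW] == pytest.approx(20.0)
        assert flow.loc["soybeans", "corn"] == pytest.approx(50.0)
        assert flow.loc["soybeans", "soybeans"] == pytest.approx(60.0)
        # only county 0 changes dominant crop (county 1's baseline corn/soy tie
        # resolves to corn, which it keeps)
        assert sw["pct_switched"] == pytest.approx(25.0)

    def test_all_fallow_counts_as_switch(self):
        base = np.array([[50.0, 50.0, 0.0]])
        new = np.zeros((1, 3))
        sw = al.summarize_switching(new, base, self.CROPS)
        assert sw["pct_switched"] == 100.0
        assert sw["fallow_fraction"] == 1.0


class TestMonteCarlo:
    @pytest.fixture(scope="class")
    def fits(self, multi_world):
        draws = {}
        for crop in ("corn", "soybeans", "wheat"):
            model = hier.build_model(
                multi_world.panel_result.panel, multi_world.covariates, hier.ModelSpec(crop=crop)
            )
            draws[crop] = hier.fit(model, chains=1, warmup=150, draws=120, seed=3)
        return draws

    def _scenarios(self, multi_world):
        clim = multi_world.panel_result.climatology
        return [
            synth.ClimateScenario(label="baseline", predictors=clim),
            synth.generate_scenario(
                clim, {c: {"edd": 1.0} for c in ("corn", "soybeans", "wheat")}, "warm", seed=1
            ),
        ]

    def test_dominance_and_interval_endpoints(self, multi_world, fits):
        allocs, outcome = al.monte_carlo_optimize(
            fits,
            multi_world.economics,
            multi_world.covariates,
            self._scenarios(multi_world),
            n_draws_used=8,
            seed=11,
        )
        pd_draw = outcome.per_draw
        assert (pd_draw["profit_opt"] >= pd_draw["profit_sq"] - 1e-6).all()
        assert (pd_draw["duality_gap"] <= 1e-6).all()
        # interval endpoints are the empirical 2.5/97.5 quantiles
        base = pd_draw[pd_draw["period"] == "baseline"]["profit_opt"].to_numpy()
        row = outcome.summary.query("period == 'baseline' and statistic == 'profit_opt'").iloc[0]
        assert row["lo"] == pytest.approx(np.quantile(base, 0.025))
        assert row["hi"] == pytest.approx(np.quantile(base, 0.975))

    def test_single_draw_degenerates_to_point(self, multi_world, fits):
        _, outcome = al.monte_carlo_optimize(
            fits,
            multi_world.economics,
            multi_world.covariates,
            self._scenarios(multi_world)[:1],
            n_draws_used=1,
            seed=12,
        )
        s = outcome.summary
        np.testing.assert_allclose(s["lo"], s["mean"], rtol=1e-12)
        np.testing.assert_allclose(s["hi"], s["mean"], rtol=1e-12)

    def test_too_many_draws_rejected(self, multi_world, fits):
        with pytest.raises(ValueError, match="exceeds"):
            al.monte_carlo_optimize(
                fits,
                multi_world.economics,
                multi_world.covariates,
                self._scenarios(multi_world)[:1],
                n_draws_used=10_000,
            )
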