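"""The hierarchical yield model: density, sampler behaviour, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cropshift import hier, ols, synth


def _toy_panel():
    """3 counties x 2 years, fixed numbers."""
    rng = np.random.default_rng(99)
    rows = []
    for cid in ("A", "B", "C"):
        for year in (1990, 1991):
            rows.append(
                {
                    "county_id": cid,
                    "year": year,
                    "crop": "corn",
                    "log_yield": rng.normal(5, 0.3),
                    "t": year - 1990,
                    "cdi": rng.normal(),
                    "gdd": rng.normal(),
                    "edd": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


def _toy_covariates():
    cov = synth.generate_counties(3, seed=1)
    cov["county_id"] = ["A", "B", "C"]
    return cov


class TestLogPosterior:
    def test_matches_hand_coded_density(self):
        """The model's unnormalized log-posterior equals an independent
        term-by-term summation of normal/half-normal log-densities."""
        panel, cov = _toy_panel(), _toy_covariates()
        model = hier.build_model(panel, cov, hier.ModelSpec(crop="corn"))
        rng = np.random.default_rng(2)
        gamma = rng.normal(0, 0.5, (5, 7))
        theta = rng.normal(0, 1, (3, 5))
        theta[:, 0] += 5
        sigma_group = np.array([0.2, 0.05, 0.1, 0.1, 0.15])
        log_sigma = np.log(0.25)
        got = model.log_posterior(gamma, theta, sigma_group, log_sigma)

        # independent summation
        want = 0.0
        idx = {"A": 0, "B": 1, "C": 2}
        for _, row in panel.iterrows():
            i = idx[row["county_id"]]
            mu = theta[i, 0] + (
                theta[i, 1] * row["t"]
                + theta[i, 2] * row["cdi"]
                + theta[i, 3] * row["gdd"]
                + theta[i, 4] * row["edd"]
            )
            want += stats.norm.logpdf(row["log_yield"], mu, 0.25)
        for i in range(3):
            for k in range(5):
                m = gamma[k, 0] + float(model.W[i, 1:] @ gamma[k, 1:])
                want += stats.norm.logpdf(theta[i, k], m, sigma_group[k])
        want += stats.norm.logpdf(gamma, 0, 5).sum()
        want += stats.halfnorm.logpdf(sigma_group, scale=2.5).sum()
        want += stats.halfnorm.logpdf(0.25, scale=2.5) + log_sigma
        assert got == pytest.approx(want, rel=1e-12)

    def test_county_variance_mode_density(self):
        panel, cov = _toy_panel(), _toy_covariates()
        model = hier.build_model(panel, cov, hier.ModelSpec(crop="corn", variance_mode="county"))
        rng = np.random.default_rng(3)
        gamma = rng.normal(0, 0.5, (5, 7))
        theta = rng.normal(0, 1, (3, 5))
        log_sigma = np.log([0.2, 0.3, 0.25])
        sg = np.full(5, 0.2)
        a = model.log_posterior(gamma, theta, sg, log_sigma, mu_logsigma=-1.4, tau_logsigma=0.5)
        # shifting one county's log-SD changes the density
        log_sigma2 = log_sigma.copy()
        log_sigma2[0] += 0.1
        b = model.log_posterior(gamma, theta, sg, log_sigma2, mu_logsigma=-1.4, tau_logsigma=0.5)
        assert a != b


class TestBuildModel:
    def test_missing_covariate_county_listed(self):
        panel, cov = _toy_panel(), _toy_covariates()
        with pytest.raises(ValueError, match="B"):
            hier.build_model(panel, cov[cov["county_id"] != "B"], hier.ModelSpec(crop="corn"))

    def test_nonpositive_yield_rejected(self):
        panel, cov = _toy_panel(), _toy_covariates()
        panel = panel.drop(columns="log_yield")
        panel["yield"] = [100, 90, 80, 70, -1, 60]
        with pytest.raises(ValueError, match="non-positive"):
            hier.build_model(panel, cov, hier.ModelSpec(crop="corn"))

    def test_unknown_crop_rejected(self):
        with pytest.raises(ValueError, match="no rows"):
            hier.build_model(_toy_panel(), _toy_covariates(), hier.ModelSpec(crop="rice"))


class TestSampler:
    def test_seeded_determinism(self, corn_world):
        model = hier.build_model(
            corn_world.panel_result.panel, corn_world.covariates, hier.ModelSpec(crop="corn")
        )
        a = hier.fit(model, chains=1, warmup=50, draws=50, seed=5)
        b = hier.fit(model, chains=1, warmup=50, draws=50, seed=5)
        np.testing.assert_array_equal(a.gamma, b.gamma)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_location_equivariance(self, corn_world, corn_fit):
        """Adding a constant to all log-yields shifts the intercept level
        only; slope posteriors are unchanged up to Monte Carlo error."""
        shifted = corn_world.panel_result.panel.copy()
        shifted["log_yield"] += 1.0
        model = hier.build_model(shifted, corn_world.covariates, hier.ModelSpec(crop="corn"))
        d2 = hier.fit(model, chains=2, warmup=300, draws=400, seed=7)
        a0 = corn_fit.stacked("gamma").mean(axis=0)[0, 0]
        a0_shift = d2.stacked("gamma").mean(axis=0)[0, 0]
        assert a0_shift - a0 == pytest.approx(1.0, abs=0.05)
        b = corn_fit.stacked("theta").mean(axis=0)[:, 1:]
        b_shift = d2.stacked("theta").mean(axis=0)[:, 1:]
        assert np.abs(b - b_shift).max() < 0.02

    def test_single_county_fit_runs_in_both_variance_modes(self):
        cfg = synth.GeneratorConfig(crops=("corn",), unsuitable_quantile=0.0, dropout_rate=0.0)
        cov = synth.generate_counties(2, seed=30, config=cfg)
        truth = synth.generate_true_params(None, cov, seed=31, config=cfg)
        pr = synth.generate_panel(truth, cov, 20, seed=32, config=cfg)
        panel = pr.panel[pr.panel["county_id"] == pr.panel["county_id"].iloc[0]]
        for mode in ("uniform", "county"):
            model = hier.build_model(panel, cov, hier.ModelSpec(crop="corn", variance_mode=mode))
            d = hier.fit(model, chains=1, warmup=50, draws=50, seed=6)
            expected = (1, 50, 1) if mode == "county" else (1, 50)
            assert d.sigma.shape == expected

    def test_large_pinned_sds_match_per_county_ols(self):
        """With between-county SDs pinned huge, pooling vanishes and county
        coefficients match their individual least-squares fits."""
        cfg = synth.GeneratorConfig(crops=("corn",), unsuitable_quantile=0.0, dropout_rate=0.0)
        cov = synth.generate_counties(5, seed=33, config=cfg)
        truth = synth.generate_true_params(None, cov, seed=34, config=cfg)
        pr = synth.generate_panel(truth, cov, 80, seed=35, config=cfg)
        spec = hier.ModelSpec(crop="corn", fixed_group_sds=np.full(5, 1e3))
        model = hier.build_model(pr.panel, cov, spec)
        d = hier.fit(model, chains=2, warmup=200, draws=600, seed=8)
        theta_hat = d.stacked("theta").mean(axis=0)
        for i, cid in enumerate(model.county_ids):
            sub = pr.panel[pr.panel["county_id"] == cid]
            X = np.column_stack([np.ones(len(sub)), sub[["t", "cdi", "gdd", "edd"]].to_numpy()])
            coef, *_ = np.linalg.lstsq(X, sub["log_yield"].to_numpy(), rcond=None)
            assert np.abs(theta_hat[i] - coef).max() < 0.02

    def test_small_pinned_sds_match_interacted_ols(self, corn_world):
        """Group SDs pinned near zero collapse the model onto the
        covariate-interacted regression."""
        pan, cov = corn_world.panel_result.panel, corn_world.covariates
        spec = hier.ModelSpec(crop="corn", fixed_group_sds=np.full(5, 1e-4))
        model = hier.build_model(pan, cov, spec)
        d = hier.fit(model, chains=2, warmup=200, draws=2000, seed=9)
        theta_hat = d.stacked("theta").mean(axis=0)
        f = ols.fit_ols(pan, cov, ols.OlsSpec("ols3", "corn"))
        cov_fit = cov.set_index("county_id").loc[model.county_ids].reset_index()
        Wz = f.scaler.transform(cov_fit, "corn")
        co = f.coef
        theta_ols = np.column_stack(
            [np.ones(len(Wz)) * co[0] + Wz @ co[1:7]]
            + [co[7 + k] + Wz @ co[11 + 6 * k : 17 + 6 * k] for k in range(4)]
        )
        assert np.abs(theta_hat - theta_ols).max() < 0.02


class TestPrediction:
    def test_observed_county_returns_fitted_draws(self, corn_world, corn_fit):
        cov = corn_world.covariates
        pred = hier.predict_coefficients(corn_fit, cov.iloc[[0]])
        cid = cov["county_id"].iloc[0]
        i = corn_fit.county_index(cid)
        np.testing.assert_array_equal(pred.theta[:, 0, :], corn_fit.stacked("theta")[:, i, :])
        assert pred.observed[0]

    def test_sign_agreement_counting(self):
        assert hier.sign_agreement(np.array([-1.0, -2.0, -3.0, 1.0])) == 0.75
        assert hier.sign_agreement(np.array([1.0, 2.0])) == 1.0

    def test_unobserved_county_has_wider_spread(self, corn_world, corn_fit):
        cov = corn_world.covariates.copy()
        new = cov.iloc[[0]].copy()
        new["county_id"] = "ZZZZ"
        both = pd.concat([cov.iloc[[0]], new], ignore_index=True)
        pred = hier.predict_coefficients(corn_fit, both, seed=1)
        sd_obs = pred.theta[:, 0, :].std(axis=0)
        sd_new = pred.theta[:, 1, :].std(axis=0)
        assert np.all(sd_new > sd_obs)

    def test_posterior_predict_zero_predictors_is_alpha(self, corn_world, corn_fit):
        cid = corn_fit.county_ids[0]
        mu = hier.posterior_predict_log_yield(corn_fit, [0, 0, 0, 0], cid)
        i = corn_fit.county_index(cid)
        np.testing.assert_allclose(mu, corn_fit.stacked("theta")[:, i, 0])

    def test_posterior_predict_linearity(self, corn_fit):
        cid = corn_fit.county_ids[0]
        i = corn_fit.county_index(cid)
        alpha = corn_fit.stacked("theta")[:, i, 0]
        a = hier.posterior_predict_log_yield(corn_fit, [0, 0, 1, 0], cid)
        b = hier.posterior_predict_log_yield(corn_fit, [0, 0, 2, 0], cid)
        np.testing.assert_allclose(b - alpha, 2 * (a - alpha), atol=1e-12)

    def test_predictive_noise_widens_distribution(self, corn_fit):
        cid = corn_fit.county_ids[0]
        mean_fn = hier.posterior_predict_log_yield(corn_fit, [0, 1, 1, 1], cid)
        noisy = hier.posterior_predict_log_yield(corn_fit, [0, 1, 1, 1], cid, include_noise=True)
        sigma = float(corn_fit.stacked("sigma").mean())
        assert noisy.std() > mean_fn.std()
        assert noisy.std() == pytest.approx(np.sqrt(mean_fn.std() ** 2 + sigma**2), rel=0.1)

    def test_point_predict_is_mean_parameter_evaluation(self, corn_world, corn_fit):
        rows = corn_world.panel_result.panel.head(20)
        got = hier.point_predict(corn_fit, rows)
        # linear map: evaluating at averaged parameters == averaging predictions
        th = corn_fit.stacked("theta")
        X = np.column_stack([np.ones(len(rows)), rows[["t", "cdi", "gdd", "edd"]].to_numpy()])
        idx = [corn_fit.county_index(c) for c in rows["county_id"]]
        per_draw = np.stack(
            [np.einsum("rj,rj->r", X, th[s, idx, :]) for s in range(th.shape[0])]
        )
        np.testing.assert_allclose(got, per_draw.mean(axis=0), atol=1e-10)

    def test_point_predict_single_draw_identity(self, corn_world, corn_fit):
        sub = hier.PosteriorDraws(
            spec=corn_fit.spec,
            county_ids=corn_fit.county_ids,
            scaler=corn_fit.scaler,
            gamma=corn_fit.gamma[:1, :1],
            theta=corn_fit.theta[:1, :1],
            sigma_group=corn_fit.sigma_group[:1, :1],
            sigma=corn_fit.sigma[:1, :1],
        )
        rows = corn_world.panel_result.panel.head(5)
        got = hier.point_predict(sub, rows)
        th = sub.theta[0, 0]
        X = np.column_stack([np.ones(5), rows[["t", "cdi", "gdd", "edd"]].to_numpy()])
        idx = [sub.county_index(c) for c in rows["county_id"]]
        np.testing.assert_allclose(got, np.einsum("rj,rj->r", X, th[idx]), atol=1e-12)

    def test_point_predict_unseen_county_uses_covariate_path(self, corn_world, corn_fit):
        rows = corn_world.panel_result.panel.head(3).copy()
        rows["county_id"] = "NEW01"
        with pytest.raises(KeyError):
            hier.point_predict(corn_fit, rows)
        cov_new = corn_world.covariates.iloc[[0]].copy()
        cov_new["county_id"] = "NEW01"
        got = hier.point_predict(corn_fit, rows, covariates=cov_new)
        assert np.isfinite(got).all()


class TestRecoverySmall:
    def test_hyper_means_within_posterior_uncertainty(self, corn_world, corn_fit):
        """On model-faithful data the posterior concentrates near the
        generating hyperparameters (small-n smoke version)."""
        truth = corn_world.truth.crops["corn"]
        g = corn_fit.stacked("gamma")
        mean, sd = g.mean(axis=0), g.std(axis=0)
        true_g = np.column_stack([truth.hyper.a, truth.hyper.loadings])
        z = np.abs(mean - true_g) / sd
        assert z.max() < 4.5  # generous at 40 counties
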