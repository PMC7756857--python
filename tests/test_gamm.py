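"""Penalized IRLS mixed-model core: closed forms, GLM equivalence, REML,
prediction curves, Moran's I, decay comparison and the spray-response fits."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import linalg
from scipy.special import logit

from vinescape import gamm
from vinescape.gamm import (
    GAMMSpec,
    compare_decay_rates,
    deviance_explained,
    fit_gamm,
    morans_i,
    predict_curve,
    threshold_response_models,
)


class TestClosedForms:
    def test_poisson_intercept_is_log_mean(self):
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y"),
            pd.DataFrame({"y": [2, 4]}),
        )
        assert fit.beta[0] == pytest.approx(np.log(3.0), abs=1e-8)
        np.testing.assert_allclose(fit.fitted, 3.0, atol=1e-7)

    def test_binomial_intercept_is_logit_proportion(self):
        df = pd.DataFrame({"succ": [1, 1, 1], "m": [4, 3, 3]})
        fit = fit_gamm(
            GAMMSpec(family="binomial", response=("succ", "m")), df
        )
        assert fit.beta[0] == pytest.approx(logit(0.3), abs=1e-8)

    def test_poisson_deviance_hand_example(self):
        """y=(1,3): an exact fit explains 100% of the hand-computed null
        deviance 2[(1 ln(1/2) + 1) + (3 ln(3/2) - 1)]."""
        df = pd.DataFrame({"y": [1, 3], "x": [0.0, 1.0]})
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y", linear_terms=["x"]), df
        )
        null_dev = 2.0 * (
            (1.0 * np.log(0.5) + 1.0) + (3.0 * np.log(1.5) - 1.0)
        )
        assert fit.null_deviance == pytest.approx(null_dev, abs=1e-8)
        assert fit.deviance == pytest.approx(0.0, abs=1e-6)
        assert fit.deviance_explained == pytest.approx(1.0, abs=1e-6)

    def test_aic_matches_hand_computation_one_parameter(self):
        y = np.array([2.0, 5.0, 3.0, 7.0])
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y"),
            pd.DataFrame({"y": y}),
        )
        mu = y.mean()
        from scipy.special import gammaln

        ll = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
        assert fit.aic == pytest.approx(-2.0 * ll + 2.0, abs=1e-6)


class TestGLMEquivalence:
    """With no smooths and no random effects the fitter IS a GLM; its
    coefficients must match statsmodels IRLS to high precision."""

    @pytest.mark.parametrize("family", ["poisson", "binomial",
                                        "negative_binomial"])
    def test_single_covariate(self, family, rng):
        n = 300
        x = rng.uniform(-1, 1, n)
        eta = 0.3 + 0.8 * x
        df = pd.DataFrame({"x": x})
        if family == "binomial":
            m = rng.integers(5, 15, n).astype(float)
            succ = rng.binomial(m.astype(int), 1 / (1 + np.exp(-eta)))
            df["succ"], df["m"] = succ, m
            spec = GAMMSpec(family=family, response=("succ", "m"),
                            linear_terms=["x"])
            sm_fit = sm.GLM(
                np.column_stack([succ, m - succ]),
                sm.add_constant(x),
                family=sm.families.Binomial(),
            ).fit()
        elif family == "poisson":
            df["y"] = rng.poisson(np.exp(eta))
            spec = GAMMSpec(family=family, response="y", linear_terms=["x"])
            sm_fit = sm.GLM(
                df["y"], sm.add_constant(x), family=sm.families.Poisson()
            ).fit()
        else:
            theta = 2.0
            mu = np.exp(eta + 1.0)
            df["y"] = rng.negative_binomial(theta, theta / (theta + mu))
            spec = GAMMSpec(family=family, response="y", linear_terms=["x"],
                            theta=theta)
            sm_fit = sm.GLM(
                df["y"],
                sm.add_constant(x),
                family=sm.families.NegativeBinomial(alpha=1.0 / theta),
            ).fit()
        fit = fit_gamm(spec, df)
        np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-6)
        assert fit.deviance == pytest.approx(sm_fit.deviance, abs=1e-5)

    def test_prior_weights_match_statsmodels(self, rng):
        n = 200
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(0.5 + x))
        w = rng.integers(1, 10, n).astype(float)
        df = pd.DataFrame({"x": x, "y": y, "w": w})
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y", linear_terms=["x"],
                     weights="w"),
            df,
        )
        sm_fit = sm.GLM(
            y, sm.add_constant(x), family=sm.families.Poisson(),
            freq_weights=w,
        ).fit()
        np.testing.assert_allclose(fit.beta, sm_fit.params, atol=1e-6)


class TestSmoothingSelection:
    def test_fellner_schall_reaches_reml_optimum(self, rng):
        """The converged smoothing parameter sits at the minimum of the
        working-model REML score computed by direct grid evaluation."""
        n = 400
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(0.5 + np.sin(2 * np.pi * x)))
        df = pd.DataFrame({"x": x, "y": y})
        spec = GAMMSpec(family="poisson", response="y",
                        smooth_terms=[("x", 10)])
        fit = fit_gamm(spec, df)
        lam_hat = fit.blocks[0].lam

        X, blocks, *_ = gamm._build_design(spec, df)
        fam = gamm._make_family("poisson")
        mu, eta = fit.fitted, fit.eta
        dmu = fam.mu_eta(eta)
        w = dmu**2 / np.maximum(fam.variance(mu), 1e-10)
        z = eta + (y - mu) / dmu
        crits = []
        for lam in np.exp(
            np.linspace(np.log(lam_hat) - 3, np.log(lam_hat) + 3, 121)
        ):
            blocks[0].lam = lam
            S = gamm._penalty_matrix(X.shape[1], blocks)
            H = (X * w[:, None]).T @ X
            beta = np.linalg.solve(H + S, (X * w[:, None]).T @ z)
            crits.append(
                (gamm._reml_criterion(X, w, z, blocks, beta), lam)
            )
        best_lam = min(crits)[1]
        assert abs(np.log(best_lam / lam_hat)) < 0.11

    def test_infinite_penalty_collapses_to_linear(self, rng):
        """As lambda -> inf the smooth's curvature dies: fitted values match
        an ordinary log-linear GLM."""
        n = 300
        x = rng.uniform(0, 1, n)
        y = rng.poisson(np.exp(0.5 + 0.8 * x))
        df = pd.DataFrame({"x": x, "y": y})
        spec = GAMMSpec(family="poisson", response="y",
                        smooth_terms=[("x", 10)])
        X, blocks, *_ = gamm._build_design(spec, df)
        blocks[0].lam = 1e12
        fam = gamm._make_family("poisson")
        beta, mu, *_ = gamm._pirls(
            X, y.astype(float), np.ones(n), fam, blocks, update_lambda=False
        )
        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(mu, glm.fittedvalues, rtol=1e-4)

    def test_random_intercept_variance_recovery(self, rng):
        """Poisson counts with a known group intercept SD: the estimated
        variance component lands near the truth."""
        n_groups, per = 80, 30
        u = rng.normal(0, 0.6, n_groups)
        g = np.repeat(np.arange(n_groups), per)
        y = rng.poisson(np.exp(1.0 + u[g]))
        df = pd.DataFrame({"y": y, "g": g})
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y", random_effects=["g"]),
            df,
        )
        assert 0.2 < fit.re_variance["g"] < 0.7  # truth 0.36

    def test_coverage_of_linear_effect(self, rng):
        """Simulation check: the Wald 95% CI for a known slope covers the
        truth in most replicates."""
        hits = 0
        reps = 40
        for _ in range(reps):
            x = rng.uniform(-1, 1, 500)
            y = rng.poisson(np.exp(0.2 + 0.7 * x))
            fit = fit_gamm(
                GAMMSpec(family="poisson", response="y",
                         linear_terms=["x"]),
                pd.DataFrame({"x": x, "y": y}),
            )
            sl = fit.term_cols["x"]
            se = np.sqrt(fit.cov[sl, sl][0, 0])
            b = fit.beta[sl][0]
            hits += b - 1.96 * se <= 0.7 <= b + 1.96 * se
        assert hits >= int(0.9 * reps)


class TestDevianceExplained:
    def test_pairing_and_mismatch_guard(self, rng):
        x = rng.uniform(0, 1, 100)
        g = np.repeat(np.arange(10), 10)
        y = rng.poisson(np.exp(0.5 + 0.5 * x + 0.4 * rng.normal(size=10)[g]))
        df = pd.DataFrame({"x": x, "y": y, "g": g})
        spec = GAMMSpec(family="poisson", response="y", linear_terms=["x"],
                        random_effects=["g"])
        fit_w = fit_gamm(spec, df)
        fit_wo = fit_gamm(gamm.strip_random_effects(spec), df)
        de_w, de_wo = deviance_explained(fit_w, fit_wo)
        assert 0.0 <= de_wo <= de_w <= 1.0
        with pytest.raises(ValueError):
            deviance_explained(fit_w, fit_gamm(
                gamm.strip_random_effects(spec), df.iloc[:50]
            ))


class TestPredictCurve:
    def test_intercept_only_flat_with_band(self):
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y"),
            pd.DataFrame({"y": [2, 4], "x": [0.0, 1.0]}),
        )
        with pytest.raises(ValueError):
            predict_curve(fit, "x")

    def test_band_contains_point_prediction(self, rng):
        x = rng.uniform(0, 1, 200)
        y = rng.poisson(np.exp(0.5 + x))
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y",
                     smooth_terms=[("x", 3)]),
            pd.DataFrame({"x": x, "y": y}),
        )
        c = predict_curve(fit, "x")
        assert ((c["lower"] <= c["fit"]) & (c["fit"] <= c["upper"])).all()

    def test_monotone_recovered_effect(self, rng):
        x = rng.uniform(0, 1, 400)
        m = np.full(400, 30)
        p = 1 / (1 + np.exp(-(-2.0 + 1.5 * x)))
        succ = rng.binomial(m, p)
        fit = fit_gamm(
            GAMMSpec(family="binomial", response=("succ", "m"),
                     smooth_terms=[("x", 3)]),
            pd.DataFrame({"x": x, "succ": succ, "m": m}),
        )
        c = predict_curve(fit, "x")
        assert (np.diff(c["fit"]) > -1e-9).all()
        assert c["fit"].iloc[-1] > c["fit"].iloc[0]

    def test_extrapolation_warns(self, rng):
        x = rng.uniform(0, 1, 100)
        y = rng.poisson(np.exp(0.2 + x))
        fit = fit_gamm(
            GAMMSpec(family="poisson", response="y", linear_terms=["x"]),
            pd.DataFrame({"x": x, "y": y}),
        )
        with pytest.warns(UserWarning, match="extrapolat"):
            predict_curve(fit, "x", grid=np.linspace(-1, 2, 10))


class TestMoransI:
    def test_four_corner_configuration(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        res = morans_i([1.0, -1.0, -1.0, 1.0], coords)
        # direct evaluation of the formula on this configuration
        assert res.I == pytest.approx(-0.47759, abs=1e-4)
        assert res.expected == pytest.approx(-1.0 / 3.0)

    def test_spatial_gradient_detected(self, rng):
        coords = rng.uniform(0, 10, (80, 2))
        vals = coords[:, 0] + rng.normal(0, 0.3, 80)
        res = morans_i(vals, coords)
        assert res.I > 0 and res.p_value < 1e-4

    def test_null_calibration(self, rng):
        """i.i.d. residuals: ~5% rejections at the 5% level."""
        coords = rng.uniform(0, 10, (120, 2))
        rej = 0
        sims = 400
        for _ in range(sims):
            res = morans_i(rng.normal(0, 1, 120), coords)
            rej += res.p_value < 0.05
        # binomial 99.9% band around 0.05
        assert 0.02 <= rej / sims <= 0.09

    def test_degenerate_inputs(self):
        coords = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        with pytest.raises(ValueError, match="zero-variance"):
            morans_i([1.0, 1.0, 1.0, 1.0], coords)
        with pytest.raises(ValueError, match="4 sites"):
            morans_i([1.0, -1.0], coords[:2])


class TestDecayComparison:
    def _fit(self, rng, jitter=0.0):
        x = rng.uniform(0, 1, 100)
        y = rng.poisson(np.exp(0.5 + x))
        return fit_gamm(
            GAMMSpec(family="poisson", response="y", linear_terms=["x"]),
            pd.DataFrame({"x": x + jitter, "y": y}),
        )

    def test_tie_broken_by_smallest_delta(self, rng):
        state = np.random.default_rng(1)
        f = self._fit(state)
        table = compare_decay_rates({750.0: f, 250.0: f, 1250.0: f})
        assert table.attrs["winner"] == 250.0
        assert (table["delta_aic"] == 0.0).all()

    def test_differing_sample_sizes_rejected(self, rng):
        a = self._fit(np.random.default_rng(1))
        x = np.random.default_rng(2).uniform(0, 1, 50)
        y = np.random.default_rng(2).poisson(np.exp(0.5 + x))
        b = fit_gamm(
            GAMMSpec(family="poisson", response="y", linear_terms=["x"]),
            pd.DataFrame({"x": x, "y": y}),
        )
        with pytest.raises(ValueError, match="sample sizes"):
            compare_decay_rates({250.0: a, 750.0: b})

    def test_true_delta_wins_on_self_consistent_data(self, small_study,
                                                     small_tables):
        """Covariates computed at the generating decay rate (1250) yield a
        lower AIC than the same model with delta=250 covariates."""
        from vinescape import pipeline

        cfg = pipeline.PipelineConfig(
            seed=42, deltas=(250.0, 1250.0), run_powersim=False
        )
        gen_tables, _, _ = pipeline.build_model_tables(small_study, cfg)
        spec = GAMMSpec(
            family="binomial",
            response=("n_exceed", "n_visits"),
            smooth_terms=["vineyard", "shrubland"],
            random_effects=["year", "farm_id"],
        )
        fits = {}
        for d in (250.0, 1250.0):
            sub = gen_tables[d][gen_tables[d]["generation"] == 3]
            fits[d] = fit_gamm(spec, sub)
        table = compare_decay_rates(fits)
        assert table.attrs["winner"] == 1250.0


class TestThresholdResponseModels:
    def test_no_never_sprayers_is_noop(self, small_tables):
        _, season, _ = small_tables
        fits = threshold_response_models(season, set())
        assert fits["fraction"].deviance == pytest.approx(
            fits["fraction_sprayers_only"].deviance
        )

    def test_never_sprayer_exclusion_steepens_response(self, small_study,
                                                       small_tables):
        """With never-sprayers in the data the spray-vs-outbreak-fraction
        curve saturates; excluding them raises the predicted spray count at
        high exceedance fractions."""
        from vinescape import prep

        _, season, _ = small_tables
        never = prep.flag_never_sprayers(
            small_study.management, farms=small_study.farms["farm_id"]
        )
        assert len(never) > 0
        fits = threshold_response_models(season, never)
        hi = 0.8 * season["fraction_exceeded"].max()
        cb = predict_curve(fits["fraction"], "fraction_exceeded",
                           grid=[hi])
        cc = predict_curve(fits["fraction_sprayers_only"],
                           "fraction_exceeded", grid=[hi])
        assert cc["fit"].iloc[0] > cb["fit"].iloc[0]
        assert fits["ever_exceeded"].p_values["ever_exceeded"] < 0.05

    def test_all_zero_sprays_guarded(self, small_tables):
        _, season, _ = small_tables
        dead = season.copy()
        dead["spray_count"] = 0
        with pytest.raises(ValueError, match="degenerate"):
            threshold_response_models(dead, set())


class TestDegenerateResponses:
    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fit_gamm(
                GAMMSpec(family="poisson", response="y"),
                pd.DataFrame({"y": [0, 0, 0]}),
            )

    def test_binomial_needs_response_pair(self):
        with pytest.raises(ValueError, match="pair"):
            fit_gamm(
                GAMMSpec(family="binomial", response="y"),
                pd.DataFrame({"y": [0, 1]}),
            )
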