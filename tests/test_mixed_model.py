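"""REML engine: design building, oracles, Wald tests, prediction."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import divpart as dp
from divpart.mixed_model import _profiled_neg2
from divpart.pipeline import _productivity_frame, AnalysisConfig


def productivity_frame(cfg):
    table, truth = dp.generate_experiment(cfg)
    return _productivity_frame(
        table, AnalysisConfig(alteration_type=cfg.alteration_type)), truth


@pytest.fixture(scope="module")
def fitted():
    cfg = dp.SimulationConfig(seed=21, species_level=False,
                              richness_levels=(1, 2, 4, 8),
                              plots_per_richness_per_treatment=2,
                              n_years=3, n_studies=4)
    df, truth = productivity_frame(cfg)
    design = dp.build_design(df, dp.ModelSpec())
    return design, dp.reml_fit(design), truth


class TestBuildDesign:
    def test_log_richness_column(self, fitted):
        design, _, _ = fitted
        lnN = design.X[:, design.fixed_names.index("ln_richness")]
        assert set(np.round(np.exp(lnN)).astype(int)) == {1, 2, 4, 8}
        assert lnN.max() == pytest.approx(np.log(8))

    def test_study_blocks(self, fitted):
        design, _, _ = fitted
        assert len(design.blocks) == 4 == design.n_studies

    def test_three_level_coding(self):
        df = pd.DataFrame({
            "study_id": "s", "plot_id": [f"p{i}" for i in range(9)],
            "year": 1, "sown_richness": 2,
            "treatment": ["control", "NPK", "NH4NO3"] * 3,
            "resp": np.arange(9.0)})
        spec = dp.ModelSpec(response="resp",
                            fixed_terms=("intercept", "treatment"),
                            random_terms=("plot",),
                            residual_correlation="independent",
                            treatment_coding="three_level")
        design = dp.build_design(df, spec)
        assert design.fixed_names == ["intercept", "treatment[NPK]",
                                      "treatment[NH4NO3]"]
        # control rows are the reference: both indicators zero
        control = design.X[::3]
        assert np.all(control[:, 1:] == 0)

    def test_unknown_label_rejected_in_three_level(self):
        df = pd.DataFrame({
            "study_id": "s", "plot_id": ["p1", "p2"], "year": 1,
            "sown_richness": 2, "treatment": ["control", "urea"],
            "resp": [1.0, 2.0]})
        spec = dp.ModelSpec(response="resp",
                            fixed_terms=("intercept", "treatment"),
                            random_terms=("plot",),
                            residual_correlation="independent",
                            treatment_coding="three_level")
        with pytest.raises(dp.ModelError, match="urea"):
            dp.build_design(df, spec)

    def test_negative_total_biomass_rejected(self):
        df = pd.DataFrame({
            "study_id": "s", "plot_id": ["p1", "p2"], "year": 1,
            "sown_richness": 2, "treatment": "control",
            "total_biomass": [10.0, -1.0]})
        with pytest.raises(dp.ModelError, match="square-root"):
            dp.build_design(df, dp.ModelSpec(
                random_terms=("plot",), residual_correlation="independent"))


class TestRemlOracles:
    def test_gls_equals_ols_in_zero_variance_limit(self):
        cfg = dataclasses.replace(
            dp.noise_free(dp.SimulationConfig(
                seed=22, species_level=False, n_studies=3,
                richness_levels=(1, 2, 4), plots_per_richness_per_treatment=2,
                n_years=2)),
            resid_sd=2.0)  # iid noise only: GLS must reduce to OLS
        df, _ = productivity_frame(cfg)
        design = dp.build_design(df, dp.ModelSpec(
            random_terms=("study", "plot"),
            residual_correlation="independent"))
        fit = dp.reml_fit(design)
        beta_ols, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-6)

    def test_balanced_one_way_matches_closed_form(self):
        rng = np.random.default_rng(42)
        S, m = 8, 10
        y = (np.repeat(rng.normal(0, np.sqrt(2.0), S), m)
             + rng.normal(0, np.sqrt(1.5), S * m) + 5.0)
        df = pd.DataFrame({
            "study_id": np.repeat([f"s{i}" for i in range(S)], m),
            "plot_id": [f"p{i}" for i in range(S * m)], "year": 1,
            "sown_richness": 1, "treatment": "control", "resp": y})
        spec = dp.ModelSpec(response="resp", fixed_terms=("intercept",),
                            random_terms=("study",),
                            residual_correlation="independent")
        fit = dp.reml_fit(dp.build_design(df, spec), ftol=1e-15)
        gm = y.reshape(S, m).mean(axis=1)
        msb = m * np.sum((gm - gm.mean()) ** 2) / (S - 1)
        msw = np.sum((y.reshape(S, m) - gm[:, None]) ** 2) / (S * (m - 1))
        assert fit.vc["variance"].iloc[0] == pytest.approx(
            (msb - msw) / m, rel=1e-6)
        assert fit.sigma2_e == pytest.approx(msw, rel=1e-6)

    def test_loglik_matches_dense_direct_evaluation(self):
        cfg = dp.SimulationConfig(seed=23, species_level=False,
                                  richness_levels=(1, 2, 4), n_studies=3,
                                  plots_per_richness_per_treatment=2,
                                  n_years=3)
        df, _ = productivity_frame(cfg)
        design = dp.build_design(df, dp.ModelSpec())
        assert design.n_obs <= 200
        variances = dict(zip(design.random_terms,
                             [3.0, 1.0, 0.5, 0.2, 2.0, 5.0]))
        s2e, rho = 4.0, 0.3
        ll = dp.restricted_loglik(design, variances, s2e, rho)

        # dense oracle assembled independently from the ordered frame
        fr = design.frame
        n = len(fr)
        y = np.sqrt(fr["total_biomass"].to_numpy())
        lnN = np.log(fr["sown_richness"].to_numpy(float))
        T = (fr["treatment"] != dp.CONTROL).to_numpy(float)
        X = np.column_stack([np.ones(n), lnN, T, lnN * T])

        def indicators(keys):
            u = sorted(set(keys))
            return np.array([[k == v for v in u] for k in keys], float)

        study = list(fr["study_id"])
        Z = {"study": indicators(study),
             "study:ln_richness": indicators(study) * lnN[:, None],
             "study:treatment": indicators(study) * T[:, None],
             "study:ln_richness:treatment":
                 indicators(study) * (lnN * T)[:, None],
             "study:time": indicators(list(zip(study, fr["year"]))),
             "plot": indicators(list(zip(study, fr["plot_id"])))}
        plot_key = list(zip(study, fr["plot_id"]))
        years = fr["year"].to_numpy()
        V = s2e * np.array(
            [[rho ** abs(int(yi) - int(yj)) * (pi == pj)
              for yj, pj in zip(years, plot_key)]
             for yi, pi in zip(years, plot_key)])
        for t, v in variances.items():
            V += v * Z[t] @ Z[t].T
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        ll_dense = -0.5 * (np.linalg.slogdet(V)[1]
                           + np.linalg.slogdet(XtViX)[1]
                           + r @ Vi @ r + (n - X.shape[1]) * np.log(2 * np.pi))
        assert ll == pytest.approx(ll_dense, abs=1e-8)

    def test_optimum_beats_random_perturbations(self, fitted):
        design, fit, _ = fitted
        lam = np.array([row["variance"] / fit.sigma2_e
                        for _, row in fit.vc.iterrows()])
        best = _profiled_neg2(design, lam, fit.rho_hat)[0]
        rng = np.random.default_rng(0)
        for _ in range(100):
            lam_p = lam * np.exp(rng.normal(0, 0.3, lam.size))
            rho_p = np.clip(fit.rho_hat + rng.normal(0, 0.1), -0.99, 0.99)
            assert _profiled_neg2(design, lam_p, rho_p)[0] >= best - 1e-6

    def test_aic_counts_covariance_parameters(self, fitted):
        _, fit, _ = fitted
        assert fit.aic == pytest.approx(
            -2 * fit.reml_loglik + 2 * fit.n_covparams)
        assert fit.n_covparams == 6 + 1 + 1  # 6 vc + sigma2_e + rho

    def test_variances_nonnegative_and_rho_in_range(self, fitted):
        _, fit, _ = fitted
        assert (fit.vc["variance"] >= 0).all()
        assert abs(fit.rho_hat) < 1

    def test_cross_check_against_statsmodels(self):
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(7)
        S, m = 6, 30
        df = pd.DataFrame({
            "study_id": np.repeat([f"s{i}" for i in range(S)], m),
            "plot_id": [f"p{i}" for i in range(S * m)], "year": 1,
            "sown_richness": np.tile([1, 2, 4, 8, 16], S * m // 5),
            "treatment": np.tile(["control", "treated"], S * m // 2)})
        lnN = np.log(df["sown_richness"])
        T = (df["treatment"] != "control").astype(float)
        df["resp"] = (10 + 2 * lnN + 1.5 * T
                      + np.repeat(rng.normal(0, 2, S), m)
                      + rng.normal(0, 1.5, S * m))
        spec = dp.ModelSpec(response="resp",
                            fixed_terms=("intercept", "ln_richness",
                                         "treatment"),
                            random_terms=("study",),
                            residual_correlation="independent")
        fit = dp.reml_fit(dp.build_design(df, spec), ftol=1e-14)
        df["lnN"], df["T"] = lnN, T
        sm_fit = smf.mixedlm("resp ~ lnN + T", df,
                             groups=df["study_id"]).fit(reml=True)
        np.testing.assert_allclose(fit.beta, sm_fit.fe_params.values,
                                   rtol=1e-5)
        assert fit.reml_loglik == pytest.approx(sm_fit.llf, abs=1e-5)
        assert fit.vc["variance"].iloc[0] == pytest.approx(
            sm_fit.cov_re.iloc[0, 0], rel=1e-2)


class TestWald:
    def test_huge_signal_is_detected(self):
        beta = dp.FixedEffectTruth(intercept=20.0, richness_slope=10.0,
                                   treatment_effect=0.5, interaction=0.0)
        cfg = dp.SimulationConfig(seed=24, species_level=False, n_studies=6,
                                  beta=beta, resid_sd=0.5,
                                  vc=dp.VarianceComponentTruth(
                                      0.5, 0.001, 0.01, 0.0, 0.1, 0.5))
        df, _ = productivity_frame(cfg)
        fit = dp.reml_fit(dp.build_design(df, dp.ModelSpec()))
        w = dp.wald_sequential(fit).set_index("term")
        assert w.loc["ln_richness", "p"] < 1e-6

    def test_order_and_shape(self, fitted):
        _, fit, _ = fitted
        w = dp.wald_sequential(fit)
        assert list(w["term"]) == list(fit.spec.fixed_terms)
        assert (w["F"] >= 0).all()
        assert (w["ndf"] == 1).all()

    def test_single_study_flags_untestable(self):
        cfg = dp.SimulationConfig(seed=25, species_level=False, n_studies=1,
                                  richness_levels=(1, 2, 4),
                                  plots_per_richness_per_treatment=3)
        df, _ = productivity_frame(cfg)
        design = dp.build_design(df, dp.ModelSpec())
        assert design.n_studies == 1
        assert "study" in design.dropped_random
        fit = dp.reml_fit(design)
        w = dp.wald_sequential(fit).set_index("term")
        assert "untestable" in w.loc["treatment", "method"]
        assert np.isnan(w.loc["treatment", "p"])


class TestComparisonAndPrediction:
    def test_identical_fits_tie(self, fitted):
        _, fit, _ = fitted
        spec_b = dataclasses.replace(fit.spec)
        res = dp.compare_covariance(fit, fit)
        assert res["delta_aic"] == 0 and res["tie"]
        assert res["selected"] == "ar1"

    def test_mismatched_designs_rejected(self, fitted):
        design, fit, _ = fitted
        cfg = dp.SimulationConfig(seed=26, species_level=False, n_studies=2,
                                  richness_levels=(1, 2))
        df, _ = productivity_frame(cfg)
        spec = dp.ModelSpec(fixed_terms=("intercept", "ln_richness"))
        other = dp.reml_fit(dp.build_design(df, spec), compute_se=False)
        with pytest.raises(dp.ModelError):
            dp.compare_covariance(fit, other)

    def test_pooled_prediction_at_monoculture_control(self, fitted):
        _, fit, _ = fitted
        lines = dp.fitted_lines(fit, [1], treatments=(0,))
        assert lines["eta"].iloc[0] == pytest.approx(fit.beta[0])
        assert lines["response"].iloc[0] == pytest.approx(fit.beta[0] ** 2)

    def test_back_transform_nonnegative(self, fitted):
        _, fit, _ = fitted
        lines = dp.fitted_lines(fit, [1, 2, 4, 8])
        assert (lines["response"] >= 0).all()
        np.testing.assert_allclose(lines["response"], lines["eta"] ** 2)

    def test_per_study_lines_average_near_pooled(self, fitted):
        _, fit, _ = fitted
        pooled = dp.fitted_lines(fit, [1, 4, 8])
        per = dp.fitted_lines(fit, [1, 4, 8], level="per_study")
        avg = per.groupby(["richness", "treatment"])["eta"].mean()
        for _, row in pooled.iterrows():
            a = avg.loc[(row["richness"], row["treatment"])]
            # BLUPs are shrunken toward zero: means agree loosely
            assert abs(a - row["eta"]) < 2.0

    def test_grid_richness_below_one_rejected(self, fitted):
        _, fit, _ = fitted
        with pytest.raises(dp.ModelError):
            dp.fitted_lines(fit, [0.5])
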