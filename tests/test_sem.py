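import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from lesionsem.cohort import SubjectTable, generate_cohort, inject_missingness
from lesionsem.errors import SpecificationError
from lesionsem.indices import chi2_difference
from lesionsem.sem import (
    StructuralModel,
    fiml_loglik,
    fit_sem,
    saturated_moments,
)
from lesionsem.spec import ModelSpec
from lesionsem.study import (
    cognition_model_spec,
    interaction_cohort_config,
    moderation_base_spec,
)

ONE_FACTOR = ModelSpec.from_dict({
    "latents": {"f": {"indicators": ["x1", "x2", "x3"]}},
})


def one_factor_table(n=400, loadings=(0.8, 0.7, 0.6), resid=(0.6, 0.6, 0.6), seed=0):
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(n)
    df = pd.DataFrame({"group": ["HO"] * n})
    for j, (lam, sd) in enumerate(zip(loadings, resid), start=1):
        df[f"x{j}"] = lam * eta + sd * rng.standard_normal(n)
    return SubjectTable(df), eta


class TestFimlLoglik:
    def test_enumeration_oracle_five_subjects(self):
        """Casewise log-likelihood equals an explicit per-subject
        marginal-density sum on a hand-chosen missingness pattern."""
        mean = np.array([0.5, -0.2, 1.0])
        cov = np.array([[1.0, 0.3, 0.2], [0.3, 1.5, 0.4], [0.2, 0.4, 2.0]])
        Y = np.array([
            [0.1, 0.2, 0.3],
            [np.nan, 1.0, -0.5],
            [0.7, np.nan, np.nan],
            [np.nan, np.nan, 2.2],
            [-1.0, 0.5, np.nan],
        ])
        expected = 0.0
        for row in Y:
            o = ~np.isnan(row)
            expected += multivariate_normal.logpdf(
                row[o], mean[o], cov[np.ix_(o, o)])
        assert fiml_loglik(Y, mean, cov) == pytest.approx(expected, abs=1e-10)

    def test_single_subject_single_variable_is_univariate_normal(self):
        Y = np.array([[1.3]])
        val = fiml_loglik(Y, np.array([1.0]), np.array([[4.0]]))
        assert val == pytest.approx(norm.logpdf(1.3, 1.0, 2.0), abs=1e-12)

    def test_complete_data_reduces_to_multivariate_ml(self):
        table, _ = one_factor_table(n=50, seed=3)
        Y = table.numeric(["x1", "x2", "x3"])
        mean = Y.mean(axis=0)
        cov = np.cov(Y.T, ddof=0) + 0.05 * np.eye(3)
        expected = multivariate_normal.logpdf(Y, mean, cov).sum()
        assert fiml_loglik(Y, mean, cov) == pytest.approx(expected, abs=1e-10)


class TestSaturatedMoments:
    def test_em_matches_complete_case_truth_when_mcar(self):
        table, _ = one_factor_table(n=4000, seed=9)
        masked = inject_missingness(table, {"x1": {"rate": 0.2}, "x2": {"rate": 0.1}},
                                    seed=4)
        Y = masked.numeric(["x1", "x2", "x3"])
        mu, Sigma, ll = saturated_moments(Y)
        Yfull = table.numeric(["x1", "x2", "x3"])
        assert np.allclose(mu, Yfull.mean(axis=0), atol=0.06)
        assert np.allclose(Sigma, np.cov(Yfull.T, ddof=0), atol=0.08)
        # EM solution must dominate the complete-data-moments plug-in
        assert ll >= fiml_loglik(Y, Yfull.mean(axis=0), np.cov(Yfull.T, ddof=0))


class TestFitSem:
    def test_just_identified_model_is_saturated(self):
        table, _ = one_factor_table(n=300, seed=1)
        res = fit_sem(ONE_FACTOR, table)
        assert res.df == 0
        assert res.chi_square < 1e-6
        assert res.indices["srmr"] < 1e-6
        assert res.indices["cfi"] == pytest.approx(1.0)
        # implied covariance reproduces the sample covariance exactly
        Y = table.numeric(["x1", "x2", "x3"])
        _, Sigma_full = res.model.implied_moments(res.params.to_numpy())
        assert np.allclose(Sigma_full[:3, :3], np.cov(Y.T, ddof=0), atol=1e-5)

    def test_nested_battery_degrees_of_freedom_hand_count(self):
        """Ten indicators: 55 covariance moments; free covariance-side
        parameters: 16 loadings + 10 residuals = 26, so df = 29."""
        model = StructuralModel(cognition_model_spec(),
                                generate_cohort_cognition(seed=0))
        assert model.compiled.p == 10
        assert model.df == 10 * 11 // 2 - 26

    def test_loading_recovery_large_n(self):
        # structural effects off so both factors have unit variance and
        # the CFA loadings are directly comparable to the generator's
        cfg = interaction_cohort_config(n_total=10_000, omega_ef=0.0,
                                        beta_wml_ef=0.0, beta_conn_ef=0.0, seed=12)
        table = generate_cohort(cfg)
        res = fit_sem(moderation_base_spec(), table)
        truth = {"conn=~z1": 0.16, "conn=~z2": 0.14, "conn=~z3": 0.15,
                 "ef=~ef1": 0.8, "ef=~ef2": 0.7, "ef=~ef3": 0.6}
        for name, lam in truth.items():
            assert res.params[name] == pytest.approx(lam, abs=0.05)

    def test_noise_free_just_identified_recovery(self):
        """With zero residual noise the engine reproduces the generating
        loadings to four decimals."""
        rng = np.random.default_rng(2)
        eta = rng.standard_normal(500)
        df = pd.DataFrame({"group": ["HO"] * 500})
        for j, lam in enumerate((1.0, 0.7, 0.4), start=1):
            df[f"x{j}"] = lam * eta + 1e-4 * rng.standard_normal(500)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_sem(ONE_FACTOR, SubjectTable(df))
        sign = np.sign(res.params["f=~x1"])
        lam1 = sign * res.params["f=~x1"]
        assert lam1 == pytest.approx(eta.std(ddof=0), abs=1e-3)
        assert sign * res.params["f=~x2"] / lam1 == pytest.approx(0.7, abs=1e-4)
        assert sign * res.params["f=~x3"] / lam1 == pytest.approx(0.4, abs=1e-4)

    def test_fiml_equals_complete_data_ml_without_missingness(self):
        table, _ = one_factor_table(n=200, seed=5)
        res = fit_sem(ONE_FACTOR, table)
        mu, Sigma_full = res.model.implied_moments(res.params.to_numpy())
        Y = table.numeric(["x1", "x2", "x3"])
        direct = multivariate_normal.logpdf(Y, mu[:3], Sigma_full[:3, :3]).sum()
        assert res.loglik == pytest.approx(direct, abs=1e-8)

    def test_adding_free_parameter_never_decreases_loglik(self):
        four = ModelSpec.from_dict({
            "latents": {"f": {"indicators": ["x1", "x2", "x3", "x4"]}},
        })
        table, _ = one_factor_table(n=250, loadings=(0.8, 0.7, 0.6, 0.5),
                                    resid=(0.6, 0.6, 0.6, 0.6), seed=6)
        base = fit_sem(four, table)
        richer = ModelSpec.from_dict({
            "latents": {"f": {"indicators": ["x1", "x2", "x3", "x4"]}},
            "residual_covariances": [["x1", "x2"]],
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res2 = fit_sem(richer, table, restarts=3)
        assert res2.loglik >= base.loglik - 1e-6

    def test_non_identified_spec_rejected_before_optimization(self):
        spec = ModelSpec.from_dict({
            "latents": {"f": {"indicators": ["x1", "x2"]}},
            "residual_covariances": [["x1", "x2"]],
        })
        table, _ = one_factor_table(n=50, seed=8)
        with pytest.raises(SpecificationError):
            StructuralModel(spec, table)

    def test_structural_beta_recovery_bias(self):
        """Across 60 cohorts at n = 230 the mean bias of the structural
        coefficients is below 0.03 in absolute value."""
        b_wml, b_conn = [], []
        spec = moderation_base_spec().with_paths([("wml_ratio", "ef"), ("conn", "ef")])
        for rep in range(60):
            cfg = interaction_cohort_config(n_total=230, omega_ef=0.0, seed=30_000 + rep)
            table = generate_cohort(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = fit_sem(spec, table, compute_se=False, restarts=2)
            b_wml.append(res.params["ef~wml_ratio"])
            b_conn.append(res.params["ef~conn"])
        assert abs(np.mean(b_wml) - (-0.9)) < 0.03 + 2 * np.std(b_wml) / np.sqrt(60)
        assert abs(np.mean(b_conn) - 0.3) < 0.03 + 2 * np.std(b_conn) / np.sqrt(60)


class TestStandardize:
    def test_rescaling_indicator_leaves_beta_unchanged(self):
        table, _ = one_factor_table(n=500, seed=10)
        res1 = fit_sem(ONE_FACTOR, table)
        data2 = table.data.copy()
        data2["x1"] = 10.0 * data2["x1"]
        res2 = fit_sem(ONE_FACTOR, SubjectTable(data2))
        assert res2.params["f=~x1"] == pytest.approx(10.0 * res1.params["f=~x1"], rel=1e-4)
        assert abs(res2.standardized["f=~x1"]) == pytest.approx(
            abs(res1.standardized["f=~x1"]), abs=1e-6)

    def test_prestandardized_variables_beta_equals_b(self):
        rng = np.random.default_rng(3)
        eta = rng.standard_normal(100_000)
        df = pd.DataFrame({"group": ["HO"] * eta.size})
        for j, lam in enumerate((0.7, 0.6, 0.5), start=1):
            x = lam * eta + np.sqrt(1 - lam**2) * rng.standard_normal(eta.size)
            df[f"x{j}"] = x
        res = fit_sem(ONE_FACTOR, SubjectTable(df))
        for j in (1, 2, 3):
            name = f"f=~x{j}"
            assert res.standardized[name] == pytest.approx(res.params[name], abs=0.01)

    def test_zero_path_standardizes_to_zero(self):
        table, _ = one_factor_table(n=300, seed=11)
        data = table.data.copy()
        data["w"] = np.random.default_rng(0).standard_normal(len(data))
        spec = ONE_FACTOR.with_paths([("w", "f")])
        res = fit_sem(spec, SubjectTable(data))
        assert abs(res.standardized["f~w"]) < 0.2
        assert np.sign(res.standardized["f~w"] + 1e-12) == np.sign(res.params["f~w"] + 1e-12)


class TestFactorScores:
    def test_deterministic_indicator_gives_exact_score(self):
        """Loading one and (near) zero residual make the score equal the
        indicator value."""
        n = 60
        rng = np.random.default_rng(4)
        eta = rng.standard_normal(n)
        df = pd.DataFrame({"group": ["HO"] * n, "x1": eta,
                           "x2": 0.5 * eta + rng.standard_normal(n),
                           "x3": 0.4 * eta + rng.standard_normal(n)})
        model = StructuralModel(ONE_FACTOR, SubjectTable(df))
        cm = model.compiled
        theta = np.zeros(cm.n_free)
        for k, pr in enumerate(cm.params):
            if pr.name == "f=~x1":
                theta[k] = 1.0
            elif pr.name in ("f=~x2", "f=~x3"):
                theta[k] = 0.5
            elif pr.name == "x1~~x1":
                theta[k] = 1e-10
            elif pr.kind == "S" and pr.i == pr.j:
                theta[k] = 1.0
        scores = model.factor_scores(theta)
        assert np.allclose(scores["f"], df["x1"], atol=1e-6)

    def test_score_correlation_reaches_reliability_bound(self):
        cfg = interaction_cohort_config(n_total=2000, omega_ef=0.0, seed=14)
        table = generate_cohort(cfg)
        res = fit_sem(moderation_base_spec(), table)
        scores = res.factor_scores()
        lam = np.array([0.8, 0.7, 0.6])
        th = np.array([0.36, 0.36, 0.36])
        Sigma = np.outer(lam, lam) + np.diag(th)
        rel = float(lam @ np.linalg.solve(Sigma, lam))  # squared correlation bound
        r = np.corrcoef(scores["ef"], table.data["true_ef"])[0, 1]
        assert abs(r) >= np.sqrt(rel) - 0.02

    def test_scores_centered_for_standardized_latents(self):
        table, _ = one_factor_table(n=800, seed=15)
        res = fit_sem(ONE_FACTOR, table)
        scores = res.factor_scores()
        assert abs(scores["f"].mean()) < 0.02

    def test_subject_with_nothing_observed_gets_nan(self):
        table, _ = one_factor_table(n=30, seed=16)
        data = table.data.copy()
        data.loc[0, ["x1", "x2", "x3"]] = np.nan
        model = StructuralModel(ONE_FACTOR, table)
        res = model.fit()
        scores = res.factor_scores(SubjectTable(data))
        assert np.isnan(scores.loc[0, "f"])
        assert np.isfinite(scores.loc[1, "f"])


class TestChi2DifferenceCalibration:
    def test_null_true_constraint_rejection_rate(self):
        """Fixing one loading at its generating value: the likelihood-
        ratio test rejects at about its nominal 5% level (500 cohorts)."""
        free = ModelSpec.from_dict({
            "latents": {"conn": {"indicators": ["z1", "z2", "z3"]}},
        })
        constrained = ModelSpec.from_dict({
            "latents": {"conn": {"indicators": [["z1", 0.16], "z2", "z3"]}},
        })
        rej = 0
        n_rep = 500
        for rep in range(n_rep):
            cfg = interaction_cohort_config(n_total=200, seed=40_000 + rep)
            table = generate_cohort(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rfree = fit_sem(free, table, compute_se=False, restarts=1)
                rcons = fit_sem(constrained, table, compute_se=False, restarts=1)
            out = chi2_difference(rcons, rfree)
            assert out["delta_df"] == 1
            rej += out["p"] < 0.05
        assert 0.03 <= rej / n_rep <= 0.07

    def test_wrong_constraint_detected_on_large_cohort(self):
        constrained = ModelSpec.from_dict({
            "latents": {"conn": {"indicators": [["z1", 0.30], "z2", "z3"]}},
        })
        free = ModelSpec.from_dict({
            "latents": {"conn": {"indicators": ["z1", "z2", "z3"]}},
        })
        cfg = interaction_cohort_config(n_total=5000, seed=77)
        table = generate_cohort(cfg)
        rfree = fit_sem(free, table, compute_se=False)
        rcons = fit_sem(constrained, table, compute_se=False)
        assert chi2_difference(rcons, rfree)["p"] < 0.001


def generate_cohort_cognition(seed=0):
    from lesionsem.study import study_cohort_config

    cfg = study_cohort_config(seed=seed, missingness={})
    return generate_cohort(cfg)
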