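import warnings

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from lesionsem.cohort import generate_cohort
from lesionsem.errors import SpecificationError
from lesionsem.moderation import InteractionSpec, LatentModerationModel, fit_lms
from lesionsem.sem import fit_sem
from lesionsem.study import interaction_cohort_config, moderation_base_spec


def make_isp(base, **kw):
    kw.setdefault("predictor", "wml_ratio")
    kw.setdefault("moderator", "conn")
    kw.setdefault("outcomes", ("ef",))
    return InteractionSpec(base=base, **kw)


class TestInteractionSpec:
    def test_latent_moderator_needs_three_indicators(self, base_spec):
        from lesionsem.spec import ModelSpec

        thin = ModelSpec.from_dict({
            "latents": {"conn": {"indicators": ["z1", "z2"]},
                        "ef": {"indicators": ["ef1", "ef2", "ef3"]}},
        })
        with pytest.raises(SpecificationError):
            make_isp(thin)

    def test_outcome_must_be_latent_and_distinct(self, base_spec):
        with pytest.raises(SpecificationError):
            make_isp(base_spec, outcomes=("conn",))
        with pytest.raises(SpecificationError):
            make_isp(base_spec, outcomes=("nonexistent",))

    def test_minimum_quadrature_nodes(self, base_spec):
        with pytest.raises(SpecificationError):
            make_isp(base_spec, quadrature_nodes=4)


class TestExactGaussianOracle:
    def test_quadrature_matches_closed_form_marginal(self, interaction_cohort, base_spec):
        """Conditional on the observed predictor the marginal over the
        latent moderator is exactly Gaussian with a subject-specific
        rank-one covariance update; the quadrature likelihood must agree."""
        isp = make_isp(base_spec)
        model = LatentModerationModel(isp, interaction_cohort)
        theta = model._start_from_linear()
        # make the interaction active so the product term matters
        theta[model.cond.names.index(isp.interaction_name("ef"))] = 0.5
        model.loglik_obj.set_grid(theta)
        ll_quad = model.loglik_obj(theta, want_grad=False)

        cond = model.cond
        A, S, a, h, g0, gw, gc, gamma, kappa = cond.build(theta)
        B = np.linalg.solve(np.eye(cond.t) - A, np.eye(cond.t))
        P = B[: cond.p]
        Sigma = P @ S @ P.T
        w = model.loglik_obj.w
        Y = model.loglik_obj.patterns.Y
        ll_exact = 0.0
        for i in range(Y.shape[0]):
            base_i = P @ (a + w[i] * g0)
            dir_i = P @ (h + w[i] * gw)
            mu_i = base_i + (kappa + gamma * w[i]) * dir_i
            cov_i = Sigma + np.outer(dir_i, dir_i)
            ll_exact += multivariate_normal.logpdf(Y[i], mu_i, cov_i)
        assert ll_quad == pytest.approx(ll_exact, abs=1e-6)


class TestObservedModerator:
    def test_equals_product_regressor_linear_sem(self, interaction_cohort, base_spec):
        """An observed x observed interaction is exactly the linear SEM
        with a computed product regressor."""
        from lesionsem.spec import ModelSpec

        ef_only = ModelSpec.from_dict({
            "latents": {"ef": {"indicators": ["ef1", "ef2", "ef3"]}},
        })
        isp = InteractionSpec(base=ef_only, predictor="wml_ratio", moderator="z1",
                              outcomes=("ef",))
        res = fit_lms(isp, interaction_cohort, seed=0)

        data = interaction_cohort.data.copy()
        wc = data["wml_ratio"] - data["wml_ratio"].mean()
        mc = data["z1"] - data["z1"].mean()
        data["wml_ratio_c"] = wc
        data["z1_c"] = mc
        data["wml_ratio_x_z1"] = wc * mc
        spec = ef_only.with_paths([
            ("wml_ratio_c", "ef"), ("z1_c", "ef"), ("wml_ratio_x_z1", "ef")])
        direct = fit_sem(spec, data, seed=0)
        for name in direct.params.index:
            assert res.params[name] == pytest.approx(direct.params[name], abs=1e-6)
        assert res.loglik == pytest.approx(direct.loglik, abs=1e-6)


class TestLatentModeration:
    def test_null_reduction_to_linear_sem(self, null_cohort, base_spec):
        """With the interaction fixed at zero the LMS likelihood matches
        the joint-model linear SEM without the product term; the free
        estimate is near zero."""
        isp = make_isp(base_spec)
        model = LatentModerationModel(isp, null_cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fixed = model.fit(seed=0, fixed={isp.interaction_name("ef"): 0.0},
                              compute_se=False)

        data = null_cohort.data.copy()
        data["wml_ratio__c"] = data["wml_ratio"] - data["wml_ratio"].mean()
        spec = base_spec.with_paths([("wml_ratio__c", "ef"), ("conn", "ef")])
        lin = fit_sem(spec, data, compute_se=False)
        assert fixed.loglik == pytest.approx(lin.loglik, abs=0.1)

        free = LatentModerationModel(isp, null_cohort).fit(seed=0)
        assert abs(free.interaction_coefficients["ef"]) < 0.05 * 8
        assert free.loglik >= fixed.loglik - 1e-6  # nesting

    def test_recovery_single_cohort(self, interaction_cohort, base_spec):
        res = fit_lms(make_isp(base_spec), interaction_cohort, seed=0)
        t = res.interaction_test("ef")
        assert t["b"] == pytest.approx(0.8, abs=3 * t["se"])
        assert t["p"] < 0.05

    def test_scale_equivariance_of_interaction(self, interaction_cohort, base_spec):
        """Rescaling the observed predictor by c rescales the
        interaction coefficient by 1/c."""
        isp = make_isp(base_spec)
        res = fit_lms(isp, interaction_cohort, seed=0, compute_se=False)
        data = interaction_cohort.data.copy()
        data["wml_ratio"] = 4.0 * data["wml_ratio"]
        res2 = fit_lms(isp, data, seed=0, compute_se=False)
        assert res2.interaction_coefficients["ef"] == pytest.approx(
            res.interaction_coefficients["ef"] / 4.0, rel=1e-3)

    def test_rows_missing_predictor_are_dropped(self, base_spec, interaction_cohort):
        data = interaction_cohort.data.copy()
        data.loc[:4, "wml_ratio"] = np.nan
        model = LatentModerationModel(make_isp(base_spec), data)
        assert model.n_effective == len(data) - 5
        assert model.n_dropped_fixed == 5


class TestSimpleSlopes:
    def test_algebraic_identity(self, interaction_cohort, base_spec):
        res = fit_lms(make_isp(base_spec), interaction_cohort, seed=0)
        bp = res.main_effects[("wml_ratio", "ef")]
        bi = res.interaction_coefficients["ef"]
        sd = res.moderator_sd
        tab = res.slope_table("ef")
        lo = tab.loc[tab.moderator_level == -1.0, "slope"].iloc[0]
        hi = tab.loc[tab.moderator_level == 1.0, "slope"].iloc[0]
        assert lo == pytest.approx(bp - bi * sd, abs=1e-12)
        assert hi == pytest.approx(bp + bi * sd, abs=1e-12)

    def test_textbook_example_values(self, interaction_cohort, base_spec):
        """b_predictor = -0.4, b_interaction = 0.2, SD = 1 gives slopes
        -0.6 and -0.2 at -1 SD and +1 SD."""
        res = fit_lms(make_isp(base_spec), interaction_cohort, seed=0)
        res.params[res._pname("ef", "predictor")] = -0.4
        res.params[res._pname("ef", "interaction")] = 0.2
        res.params[f"conn~wml_ratio"] = 0.0  # unit moderator SD
        tab = res.slope_table("ef")
        assert tab.slope.tolist() == pytest.approx([-0.6, -0.2], abs=1e-12)

    def test_no_moderation_gives_parallel_lines(self, null_cohort, base_spec):
        isp = make_isp(base_spec)
        model = LatentModerationModel(isp, null_cohort)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(seed=0, fixed={isp.interaction_name("ef"): 0.0},
                            compute_se=False)
        tab = res.slope_table("ef")
        assert tab.slope.iloc[0] == pytest.approx(tab.slope.iloc[1], abs=1e-10)

    def test_protective_pattern_shallower_slope_at_high_connectivity(
            self, interaction_cohort, base_spec):
        """Negative lesion main effect with positive interaction: the
        +1 SD connectivity slope is strictly less negative."""
        res = fit_lms(make_isp(base_spec), interaction_cohort, seed=0)
        tab = res.slope_table("ef")
        lo = tab.loc[tab.moderator_level == -1.0, "slope"].iloc[0]
        hi = tab.loc[tab.moderator_level == 1.0, "slope"].iloc[0]
        assert lo < 0 and hi > lo

    def test_unknown_outcome_rejected(self, interaction_cohort, base_spec):
        res = fit_lms(make_isp(base_spec), interaction_cohort, seed=0,
                      compute_se=False)
        with pytest.raises(SpecificationError):
            res.slope_table("memory")

    def test_prediction_table_shape(self, interaction_cohort, base_spec):
        res = fit_lms(make_isp(base_spec), interaction_cohort, seed=0)
        tab = res.prediction_table("ef", n_grid=25)
        assert len(tab) == 50
        assert set(tab.moderator_level) == {-1.0, 1.0}
        assert (tab.upper >= tab.predicted).all()
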