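import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from lesionsem.cohort import CohortConfig, generate_cohort, inject_missingness
from lesionsem.errors import SpecificationError
from lesionsem.study import interaction_cohort_config, study_cohort_config


class TestGenerateCohort:
    def test_published_sample_sizes(self):
        table = generate_cohort(study_cohort_config(seed=1))
        assert len(table) == 230
        assert (table.group == "MCI").sum() == 90
        assert (table.group == "HO").sum() == 140

    def test_reproducibility_same_seed(self):
        cfg = study_cohort_config(seed=9)
        t1 = generate_cohort(cfg)
        t2 = generate_cohort(study_cohort_config(seed=9))
        assert_frame_equal(t1.data, t2.data)

    def test_different_seed_differs(self):
        t1 = generate_cohort(interaction_cohort_config(seed=1))
        t2 = generate_cohort(interaction_cohort_config(seed=2))
        assert not t1.data["ef1"].equals(t2.data["ef1"])

    def test_stream_stability_under_config_extension(self):
        """Adding a new variable must not perturb existing columns."""
        cfg = interaction_cohort_config(seed=4)
        t1 = generate_cohort(cfg)
        cfg2 = interaction_cohort_config(
            seed=4,
            extra_observed={"age": {"mean": 65.0, "sd": 7.6}},
        )
        t2 = generate_cohort(cfg2)
        for col in ("z1", "ef2", "wml_ratio"):
            assert t1.data[col].equals(t2.data[col])

    def test_noise_free_limit_indicator_equals_latent(self):
        cfg = interaction_cohort_config(
            n_total=50, seed=3,
            loading_matrix={"conn": [("z1", 1.0)], "ef": [("ef1", 1.0)]},
            residual_sd={"z1": 0.0, "ef1": 0.0},
            indicator_means={"z1": 0.0, "ef1": 0.0},
        )
        t = generate_cohort(cfg)
        assert np.allclose(t.data["z1"], t.data["true_conn"])
        assert np.allclose(t.data["ef1"], t.data["true_ef"])

    def test_null_interaction_ols_oracle(self):
        """With omega = 0 the product coefficient in an OLS of the true
        executive factor on (lesion, connectivity, product) is ~0."""
        cfg = interaction_cohort_config(n_total=5000, omega_ef=0.0, seed=17)
        t = generate_cohort(cfg)
        w = t.data["wml_ratio"].to_numpy()
        wc = w - w.mean()
        conn = t.data["true_conn"].to_numpy()
        X = np.column_stack([np.ones_like(w), wc, conn, wc * conn])
        beta = np.linalg.lstsq(X, t.data["true_ef"].to_numpy(), rcond=None)[0]
        assert abs(beta[3]) < 0.03
        assert beta[1] == pytest.approx(cfg.structural["beta_wml_ef"], abs=0.1)

    def test_wml_distribution_calibration(self):
        """Lesion load is right-skewed on the percent-of-TIV scale with
        the published group means and hard upper bound."""
        cfg = study_cohort_config(seed=21, n_total=20000, n_mci=7826,
                                  missingness={})
        t = generate_cohort(cfg)
        w = t.data["wml_ratio"]
        assert w.min() >= 0 and w.max() <= 2.8
        assert w.mean() == pytest.approx(0.17, abs=0.03)
        by = t.data.groupby("group")["wml_ratio"].mean()
        assert by["MCI"] > 2.0 * by["HO"]
        assert w.skew() > 2.0  # strong right skew

    def test_moment_fidelity_large_n(self):
        """At n = 50,000 the sample indicator covariance matches the
        model-implied covariance entrywise within 0.02."""
        cfg = interaction_cohort_config(n_total=50_000, omega_ef=0.0, seed=8,
                                        group_shifts={}, n_mci=0)
        t = generate_cohort(cfg)
        inds = ["z1", "z2", "z3", "ef1", "ef2", "ef3"]
        lam_conn = np.array([0.16, 0.14, 0.15, 0.0, 0.0, 0.0])
        lam_ef = np.array([0.0, 0.0, 0.0, 0.8, 0.7, 0.6])
        s = cfg.structural
        w = t.data["wml_ratio"].to_numpy()
        var_w = w.var()
        # ef = b_w * w_c + b_c * conn + zeta ; conn ~ N(0,1) independent of w
        cov_lat = np.array([
            [1.0, s["beta_conn_ef"]],
            [s["beta_conn_ef"], s["beta_wml_ef"] ** 2 * var_w + s["beta_conn_ef"] ** 2 + 1.0],
        ])
        L = np.column_stack([lam_conn, lam_ef])
        theta = np.diag([0.13**2] * 3 + [0.6**2] * 3)
        implied = L @ cov_lat @ L.T + theta
        sample = np.cov(t.data[inds].to_numpy().T, ddof=0)
        assert np.max(np.abs(sample - implied)) < 0.02

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(SpecificationError):
            CohortConfig(
                n_total=10, n_mci=2, exogenous_latents=["a", "b"],
                latent_covariances=np.array([[1.0, 2.0], [2.0, 1.0]]),
                loading_matrix={"a": [("x", 1.0)], "b": [("y", 1.0)]},
            )

    def test_n_mci_bound(self):
        with pytest.raises(SpecificationError):
            interaction_cohort_config(n_total=50, n_mci=60)


class TestInjectMissingness:
    def test_zero_rate_is_identity(self, interaction_cohort):
        out = inject_missingness(interaction_cohort, {"ef1": {"rate": 0.0}}, seed=1)
        assert_frame_equal(out.data, interaction_cohort.data)

    def test_exact_count_matches_published_footnote(self):
        """Exact-count masking reproduces the reported 91/230 missing
        lifestyle entries and the single missing lesion volume."""
        t = generate_cohort(study_cohort_config(seed=2))
        assert int(t.data["lifestyle_index"].isna().sum()) == 91
        assert int(t.data["wml_ratio"].isna().sum()) == 1
        missing_wml_groups = t.data.loc[t.data["wml_ratio"].isna(), "group"]
        assert (missing_wml_groups == "MCI").all()

    def test_mar_on_group_masks_only_that_group(self, interaction_cohort):
        out = inject_missingness(
            interaction_cohort,
            {"ef1": {"rate": 0.5, "mechanism": "MAR-on-group", "group": "HO"}},
            seed=5)
        miss = out.data["ef1"].isna()
        assert miss.any()
        assert (out.data.loc[miss, "group"] == "HO").all()

    def test_observed_values_untouched(self, interaction_cohort):
        out = inject_missingness(interaction_cohort, {"ef1": {"rate": 0.3}}, seed=6)
        kept = ~out.data["ef1"].isna()
        assert np.allclose(out.data.loc[kept, "ef1"],
                           interaction_cohort.data.loc[kept, "ef1"])

    def test_unknown_variable_rejected(self, interaction_cohort):
        with pytest.raises(SpecificationError):
            inject_missingness(interaction_cohort, {"nope": {"rate": 0.1}})

    def test_rate_out_of_bounds_rejected(self, interaction_cohort):
        with pytest.raises(SpecificationError):
            inject_missingness(interaction_cohort, {"ef1": {"rate": 1.2}})
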