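"""Canned study-design objects: default cohort configuration and the
default model specifications.

The defaults emulate a two-site ageing cohort: n = 230 (140 healthy
older, 90 MCI); a ten-test cognitive battery measuring a global factor
(``g``) with nested executive (``ef``) and memory factors; per-network
connectivity factors with Fisher-z ROI-pair indicators (fronto-parietal,
salience, default mode); a cognitive-reserve factor (education,
premorbid IQ, lifestyle); a lesion load of mean 0.17, SD 0.37, range
0 - 2.8 percent of intracranial volume, right-skewed and higher in MCI;
and structured missingness (lifestyle missing for 91 participants,
lesion volume for one MCI participant).

Raw speed scores (trail making, Stroop) load negatively on cognition;
analyses re-orient them with :func:`lesionsem.derive.invert_speed_scores`.
"""

from __future__ import annotations

import numpy as np

from .cohort import CohortConfig
from .spec import ModelSpec

__all__ = [
    "MEMORY_TESTS",
    "EF_TESTS",
    "SPEED_TESTS",
    "COGNITION_TESTS",
    "FPN_INDICATORS",
    "SALIENCE_INDICATORS",
    "DMN_INDICATORS",
    "study_cohort_config",
    "interaction_cohort_config",
    "cognition_model_spec",
    "connectivity_model_spec",
    "reserve_model_spec",
    "wml_cognition_spec",
    "moderation_base_spec",
]

MEMORY_TESTS = ["vlmt_immediate", "vlmt_delayed", "vlmt_recognition"]
EF_TESTS = ["tmt_a", "tmt_b", "stroop_interference"]
SPEED_TESTS = list(EF_TESTS)  # timed scores; higher raw value = worse
OTHER_TESTS = ["digit_span_forward", "digit_span_backward",
               "fluency_phonemic", "fluency_alternating"]
COGNITION_TESTS = MEMORY_TESTS + EF_TESTS + OTHER_TESTS

FPN_INDICATORS = ["lpfc_l_ppc_l", "lpfc_l_ppc_r", "lpfc_l_lpfc_r",
                  "lpfc_r_ppc_l", "lpfc_r_ppc_r", "ppc_l_ppc_r"]
SALIENCE_INDICATORS = ["acc_ai_l", "acc_ai_r", "ai_l_ai_r"]
DMN_INDICATORS = ["mpfc_pcc", "mpfc_lp_l", "mpfc_lp_r",
                  "pcc_lp_l", "pcc_lp_r", "lp_l_lp_r"]

#: residual covariances among connectivity pairs sharing a seed region
_DMN_RESIDUAL_COVS = [("mpfc_lp_l", "mpfc_lp_r", 0.008),
                      ("pcc_lp_l", "pcc_lp_r", 0.008)]


def study_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """Full study-like generating model at the published sample sizes.

    Structural coefficients default to a negative lesion effect on all
    cognition factors (strongest for executive function), a positive
    connectivity main effect, and a positive lesion x fronto-parietal
    interaction on executive function only — the qualitative pattern the
    downstream analyses are meant to detect.
    """
    loading = {}
    # cognition: global factor on all ten tests, nested EF and memory
    loading["g"] = [(t, -0.5 if t in SPEED_TESTS else 0.5) for t in COGNITION_TESTS]
    loading["ef"] = [(t, -0.45) for t in EF_TESTS]
    loading["memory"] = [(t, 0.45) for t in MEMORY_TESTS]
    # connectivity networks: Fisher-z indicators, factor SD 1
    loading["fpn"] = [(v, 0.16) for v in FPN_INDICATORS]
    loading["salience"] = [(v, 0.16) for v in SALIENCE_INDICATORS]
    loading["dmn"] = [(v, 0.16) for v in DMN_INDICATORS]
    # cognitive reserve: education years, premorbid IQ, lifestyle index
    loading["cr"] = [("education", 2.0), ("mwt", 1.7), ("lifestyle_index", 1.5),
                     ("salience_local_z", 0.10)]

    residual_sd = {t: 0.75 for t in COGNITION_TESTS}
    residual_sd.update({v: 0.13 for v in FPN_INDICATORS + SALIENCE_INDICATORS + DMN_INDICATORS})
    residual_sd.update({"education": 2.6, "mwt": 2.1, "lifestyle_index": 2.1,
                        "salience_local_z": 0.12})

    means = {t: 0.0 for t in COGNITION_TESTS}
    means.update({v: 0.35 for v in FPN_INDICATORS})
    means.update({v: 0.40 for v in SALIENCE_INDICATORS})
    means.update({v: 0.45 for v in DMN_INDICATORS})
    means.update({"education": 15.8, "mwt": 31.9, "lifestyle_index": 16.2,
                  "salience_local_z": 0.30})

    exo = ["fpn", "salience", "dmn", "cr"]
    # modest positive coupling between reserve and the control networks
    cov = np.eye(4)
    cov[0, 3] = cov[3, 0] = 0.25
    cov[1, 3] = cov[3, 1] = 0.25
    cov[0, 1] = cov[1, 0] = 0.30
    cov[0, 2] = cov[2, 0] = 0.20
    cov[1, 2] = cov[2, 1] = 0.20

    defaults = dict(
        n_total=230,
        n_mci=90,
        exogenous_latents=exo,
        latent_covariances=cov,
        loading_matrix=loading,
        structural={
            "beta_wml_g": -0.6, "beta_wml_ef": -0.9, "beta_wml_mem": -0.5,
            "beta_conn_ef": 0.3, "beta_conn_mem": 0.2,
            "omega_ef": 0.8, "omega_mem": 0.0,
            "beta_cvd_wml_meanlog": 0.45, "beta_cvd_ef": -0.15, "beta_cvd_mem": -0.12,
        },
        moderator="fpn",
        # log-normal matched to overall mean 0.17, SD 0.37, truncated at 2.8;
        # MCI shifted upward on the log scale (group means 0.11 vs 0.28)
        wml_distribution={"meanlog": -3.1, "sdlog": 1.32, "max": 2.8},
        group_shifts={"g": -0.55, "ef": -0.45, "memory": -0.55,
                      "wml_meanlog": 0.93, "fpn": -0.1},
        residual_sd=residual_sd,
        indicator_means=means,
        residual_covariances=list(_DMN_RESIDUAL_COVS),
        extra_observed={
            "age": {"mean": 63.0, "sd": 7.0, "group_shift": 5.6},
            "gm_volume": {"mean": 600_000.0, "sd": 50_000.0, "group_shift": -20_000.0},
            "cvd_risk": {"mean": 15.0, "sd": 6.0, "group_shift": 2.0},
            "tiv": {"mean": 1_500_000.0, "sd": 120_000.0},
        },
        missingness={
            "lifestyle_index": {"rate": 91 / 230, "mechanism": "MCAR", "exact": True},
            "wml_ratio": {"rate": 1 / 90, "mechanism": "MAR-on-group",
                          "group": "MCI", "exact": True},
        },
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def interaction_cohort_config(
    n_total: int = 230,
    omega_ef: float = 0.8,
    beta_wml_ef: float = -0.9,
    beta_conn_ef: float = 0.3,
    n_mci: int | None = None,
    seed: int = 0,
    **overrides,
) -> CohortConfig:
    """Compact one-network, one-outcome generating model.

    Used for the repeated simulation studies (recovery, type-I error,
    power), where only the moderator factor (three Fisher-z indicators)
    and the executive factor (three indicators) are needed.
    """
    if n_mci is None:
        n_mci = int(round(n_total * 90 / 230))
    loading = {
        "conn": [("z1", 0.16), ("z2", 0.14), ("z3", 0.15)],
        "ef": [("ef1", 0.8), ("ef2", 0.7), ("ef3", 0.6)],
    }
    residual_sd = {"z1": 0.13, "z2": 0.13, "z3": 0.13,
                   "ef1": 0.6, "ef2": 0.6, "ef3": 0.6}
    means = {"z1": 0.35, "z2": 0.32, "z3": 0.38, "ef1": 0.0, "ef2": 0.0, "ef3": 0.0}
    defaults = dict(
        n_total=n_total,
        n_mci=n_mci,
        exogenous_latents=["conn"],
        loading_matrix=loading,
        structural={"beta_wml_ef": beta_wml_ef, "beta_conn_ef": beta_conn_ef,
                    "omega_ef": omega_ef},
        moderator="conn",
        wml_distribution={"meanlog": -3.1, "sdlog": 1.32, "max": 2.8},
        group_shifts={"wml_meanlog": 0.93},
        residual_sd=residual_sd,
        indicator_means=means,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def cognition_model_spec(identification: str = "standardize_latent") -> ModelSpec:
    """Global cognition with nested executive and memory factors."""
    return ModelSpec.from_dict({
        "latents": {
            "g": {"indicators": COGNITION_TESTS},
            "ef": {"indicators": EF_TESTS, "nested_under": "g"},
            "memory": {"indicators": MEMORY_TESTS, "nested_under": "g"},
        },
        "identification": identification,
    })


def connectivity_model_spec(network: str = "fpn") -> ModelSpec:
    """One-network global-connectivity measurement model."""
    inds = {"fpn": FPN_INDICATORS, "salience": SALIENCE_INDICATORS,
            "dmn": DMN_INDICATORS}[network]
    spec = {"latents": {network: {"indicators": inds}}}
    if network == "dmn":
        spec["residual_covariances"] = [[a, b] for a, b, _ in _DMN_RESIDUAL_COVS]
    return ModelSpec.from_dict(spec)


def reserve_model_spec() -> ModelSpec:
    """Behavioral cognitive-reserve measurement model (just identified)."""
    return ModelSpec.from_dict({
        "latents": {"cr": {"indicators": ["education", "mwt", "lifestyle_index"]}},
    })


def wml_cognition_spec() -> ModelSpec:
    """Structural model: lesion load predicting g, ef, and memory."""
    spec = cognition_model_spec()
    return spec.with_paths([("wml_ratio", "g"), ("wml_ratio", "ef"),
                            ("wml_ratio", "memory")])


def moderation_base_spec(
    moderator: str = "conn",
    moderator_indicators=("z1", "z2", "z3"),
    outcomes=("ef",),
    outcome_indicators={"ef": ("ef1", "ef2", "ef3")},
) -> ModelSpec:
    """Separate-factor base model for the latent-moderation analyses."""
    latents = {moderator: {"indicators": list(moderator_indicators)}}
    for out in outcomes:
        latents[out] = {"indicators": list(outcome_indicators[out])}
    return ModelSpec.from_dict({"latents": latents})
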