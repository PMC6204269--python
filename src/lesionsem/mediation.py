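"""Mediation of vascular risk on cognition through lesion load.

The path model is fitted simultaneously within the SEM: the observed
predictor (CVD risk score) predicts the observed mediator (lesion
load, path ``a``) and the latent outcome directly (path ``c'``); the
mediator predicts the outcome (path ``b``). The indirect effect is the
product ``a * b``; its confidence interval comes from a seeded
nonparametric bootstrap over subjects (percentile), with a delta-method
(Sobel) interval available for comparison. The standardized indirect
effect is computed per bootstrap draw from the standardized paths.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectTable, as_subject_table
from .errors import ConvergenceWarning, SpecificationError
from .sem import StructuralModel
from .spec import ModelSpec

__all__ = ["MediationModel", "MediationResults", "fit_mediation", "correlate"]


class MediationModel:
    """Predictor -> mediator -> latent outcome path model."""

    def __init__(self, predictor, mediator, outcome_spec: ModelSpec, table,
                 outcome=None, covariates=()):
        self.table = as_subject_table(table)
        if outcome is None:
            lat_names = list(outcome_spec.latents)
            if len(lat_names) != 1:
                raise SpecificationError(
                    "outcome latent is ambiguous; pass outcome= explicitly")
            outcome = lat_names[0]
        if outcome not in outcome_spec.latents:
            raise SpecificationError(f"outcome {outcome!r} not in the outcome model")
        self.predictor, self.mediator, self.outcome = predictor, mediator, outcome
        paths = [(predictor, mediator), (mediator, outcome), (predictor, outcome)]
        spec = outcome_spec.with_paths(paths)
        if covariates:
            spec = spec.with_covariates(list(covariates))
        self.spec = spec
        self.model = StructuralModel(spec, self.table)

    def fit(self, n_boot=2000, seed=0, ci=0.95, restarts=5):
        """Point fit plus seeded percentile bootstrap for the indirect effect."""
        if n_boot < 200:
            raise SpecificationError("need n_boot >= 200 for a stable percentile interval")
        res = self.model.fit(restarts=restarts, seed=seed)
        a_name = f"{self.mediator}~{self.predictor}"
        b_name = f"{self.outcome}~{self.mediator}"
        c_name = f"{self.outcome}~{self.predictor}"
        theta_hat = res.params.to_numpy()

        rng = np.random.default_rng(seed)
        n = len(self.table)
        draws = np.empty(n_boot)
        draws_std = np.empty(n_boot)
        failures = 0
        data = self.table.data
        for bidx in range(n_boot):
            rows = rng.integers(0, n, size=n)
            btab = SubjectTable(data.iloc[rows].reset_index(drop=True))
            try:
                bmod = StructuralModel(self.spec, btab)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    bres = bmod.fit(start=theta_hat, restarts=1, compute_se=False)
                if not bres.converged:
                    failures += 1
                    draws[bidx] = draws_std[bidx] = np.nan
                    continue
                std = bres.standardized
                draws[bidx] = bres.params[a_name] * bres.params[b_name]
                draws_std[bidx] = std[a_name] * std[b_name]
            except (np.linalg.LinAlgError, ValueError, SpecificationError):
                failures += 1
                draws[bidx] = draws_std[bidx] = np.nan

        flagged = failures > 0.05 * n_boot
        if flagged:
            warnings.warn(
                f"{failures}/{n_boot} bootstrap refits failed to converge",
                ConvergenceWarning, stacklevel=2)
        alpha = (1.0 - ci) / 2.0
        ok = np.isfinite(draws)
        ci_raw = tuple(np.quantile(draws[ok], [alpha, 1 - alpha]))
        ci_std = tuple(np.quantile(draws_std[np.isfinite(draws_std)], [alpha, 1 - alpha]))
        return MediationResults(
            model=self, sem_results=res,
            a=float(res.params[a_name]), b=float(res.params[b_name]),
            c_prime=float(res.params[c_name]),
            a_std=float(res.standardized[a_name]), b_std=float(res.standardized[b_name]),
            se_a=float(res.se[a_name]), se_b=float(res.se[b_name]),
            ci=ci_std, ci_unstandardized=ci_raw, ci_level=ci,
            n_boot=n_boot, seed=seed, boot_failures=failures, flagged=flagged,
            boot_draws=draws, boot_draws_std=draws_std,
        )


class MediationResults:
    """Path coefficients a, b, c' and the indirect effect a*b with CI."""

    def __init__(self, model, sem_results, a, b, c_prime, a_std, b_std,
                 se_a, se_b, ci, ci_unstandardized, ci_level, n_boot, seed,
                 boot_failures, flagged, boot_draws, boot_draws_std):
        self.model = model
        self.sem_results = sem_results
        self.a, self.b, self.c_prime = a, b, c_prime
        self.a_std, self.b_std = a_std, b_std
        self.se_a, self.se_b = se_a, se_b
        self.ci = ci
        self.ci_unstandardized = ci_unstandardized
        self.ci_level = ci_level
        self.n_boot = n_boot
        self.seed = seed
        self.boot_failures = boot_failures
        self.flagged = flagged
        self.boot_draws = boot_draws
        self.boot_draws_std = boot_draws_std

    @property
    def indirect(self):
        return self.a * self.b

    @property
    def indirect_standardized(self):
        return self.a_std * self.b_std

    @property
    def total_effect(self):
        return self.c_prime + self.indirect

    def sobel(self):
        """Delta-method (Sobel) SE and normal-theory CI of the raw
        indirect effect, for comparison with the bootstrap interval."""
        se = math.sqrt(self.b**2 * self.se_a**2 + self.a**2 * self.se_b**2)
        z = stats.norm.ppf(0.5 + self.ci_level / 2.0)
        return {"se": se, "ci": (self.indirect - z * se, self.indirect + z * se),
                "p": 2.0 * stats.norm.sf(abs(self.indirect) / se) if se > 0 else math.nan}

    def summary(self):
        lo, hi = self.ci
        return "\n".join([
            "Mediation model (simultaneous SEM, percentile bootstrap CI)",
            f"  {self.model.predictor} -> {self.model.mediator} (a): {self.a:.4f}",
            f"  {self.model.mediator} -> {self.model.outcome} (b): {self.b:.4f}",
            f"  direct effect (c'): {self.c_prime:.4f}",
            f"  indirect a*b: {self.indirect:.4f} "
            f"(standardized {self.indirect_standardized:.4f})",
            f"  {100 * self.ci_level:.0f}% CI (standardized): [{lo:.4f}, {hi:.4f}]",
            f"  bootstrap: {self.n_boot} draws, {self.boot_failures} failures"
            + (" [FLAGGED]" if self.flagged else ""),
        ])


def fit_mediation(predictor, mediator, outcome_spec, table, n_boot=2000,
                  seed=0, **kwargs) -> MediationResults:
    fit_kwargs = {k: kwargs.pop(k) for k in list(kwargs) if k in ("ci", "restarts")}
    model = MediationModel(predictor, mediator, outcome_spec, table, **kwargs)
    return model.fit(n_boot=n_boot, seed=seed, **fit_kwargs)


def correlate(x, y):
    """Pearson correlation on pairwise-complete cases with a two-sided
    t-based p value; returns ``{"r", "p", "n"}``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(xs, ys)
    return {"r": float(r), "p": float(p), "n": int(ok.sum())}
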