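"""Known-class multigroup latent-interaction models.

Groups (healthy older vs MCI) are treated as known classes: one
optimization maximizes the sum of the per-group casewise likelihoods.
Measurement parameters (loadings, indicator intercepts, indicator
residual variances/covariances) are constrained equal across groups by
default; structural parameters — main effects, the lesion x
connectivity interaction, latent disturbances, and the moderator's
regression on the predictor — are free per group, each with its own
Wald test. Latent means are fixed at zero in every group (strong
invariance with equal means); releasing all equality constraints
(``equal_measurement=False``) is the sensitivity check.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectTable, as_subject_table
from .errors import ConvergenceWarning, SpecificationError
from .moderation import InteractionSpec, LatentModerationModel
from .sem import _lbfgs_with_restarts, start_values

__all__ = ["MultigroupModerationModel", "MultigroupResults", "fit_multigroup_lms"]


class _GroupEngine:
    """Uniform likelihood interface over one group's moderation model."""

    def __init__(self, lmm: LatentModerationModel):
        self.lmm = lmm
        self.latent = lmm.ispec.moderator_is_latent
        if self.latent:
            self.names = list(lmm.cond.names)
            self.positive = np.array([p.positive for p in lmm.cond.params])
            self.marginal_ll = lmm._ll_marg
        else:
            cm = lmm._linear_model.compiled
            self.names = list(cm.names)
            self.positive = np.array([p.positive for p in cm.params])
            self.marginal_ll = 0.0
        self.n = lmm.n_effective

    def start(self):
        if self.latent:
            th = self.lmm._start_from_linear()
            if self.lmm._grid == "posterior":
                self.lmm.loglik_obj.set_grid(th)
            return th
        return start_values(self.lmm._linear_model.compiled,
                            self.lmm._linear_model.patterns.Y)

    def loglik_grad(self, theta):
        if self.latent:
            return self.lmm.loglik_obj(theta)
        return self.lmm._linear_model.loglik_grad(theta)


class MultigroupModerationModel:
    """Simultaneous latent-interaction fit across known groups."""

    def __init__(self, ispec: InteractionSpec, table, group_var="group",
                 equal_measurement=True, grid="posterior"):
        self.ispec = ispec
        self.table = as_subject_table(table)
        self.group_var = group_var
        self.equal_measurement = equal_measurement
        data = self.table.data
        if group_var not in data.columns:
            raise SpecificationError(f"group variable {group_var!r} not in table")
        if data[group_var].isna().any():
            raise SpecificationError("every subject must carry a group label")
        self.groups = [g for g in data[group_var].unique()]
        self.engines = {}
        for g in self.groups:
            sub = data[data[group_var] == g].reset_index(drop=True)
            if len(sub) == 0:
                raise SpecificationError(f"group {g!r} is empty")
            sub = sub.copy()
            if "group" not in sub.columns:
                sub["group"] = g
            lmm = LatentModerationModel(ispec, SubjectTable(sub), grid=grid)
            self.engines[g] = _GroupEngine(lmm)

        # parameter sharing plan
        ref = self.engines[self.groups[0]]
        indicators = set(ispec.base.indicator_names())

        def is_measurement(name):
            if "=~" in name:
                return True
            if name.endswith("~1"):
                return name[:-2] in indicators
            if "~~" in name:
                left, right = name.split("~~")
                return left in indicators and right in indicators
            return False

        self.shared_names = ([n for n in ref.names if is_measurement(n)]
                             if equal_measurement and len(self.groups) > 1 else [])
        self._build_index()

    def _build_index(self):
        shared_pos = {n: k for k, n in enumerate(self.shared_names)}
        offset = len(self.shared_names)
        self.maps = {}
        self.joint_names = list(self.shared_names)
        positive = [False] * offset
        for g in self.groups:
            eng = self.engines[g]
            idx = np.empty(len(eng.names), dtype=int)
            for k, name in enumerate(eng.names):
                if name in shared_pos:
                    idx[k] = shared_pos[name]
                    positive[shared_pos[name]] = bool(eng.positive[k])
                else:
                    idx[k] = offset
                    self.joint_names.append(f"{name}@{g}")
                    positive.append(bool(eng.positive[k]))
                    offset += 1
            self.maps[g] = idx
        self.positive = np.array(positive)
        self.n_joint = offset
        self.n_total = sum(e.n for e in self.engines.values())

    # -- joint likelihood -------------------------------------------
    def loglik_grad(self, theta_joint):
        ll = 0.0
        grad = np.zeros(self.n_joint)
        for g in self.groups:
            eng = self.engines[g]
            th_g = theta_joint[self.maps[g]]
            ll_g, g_g = eng.loglik_grad(th_g)
            if not np.isfinite(ll_g) or g_g is None:
                return -np.inf, None
            ll += ll_g
            np.add.at(grad, self.maps[g], g_g)
        return ll, grad

    def _start(self):
        theta0 = np.zeros(self.n_joint)
        counts = np.zeros(self.n_joint)
        for g in self.groups:
            st = self.engines[g].start()
            np.add.at(theta0, self.maps[g], st)
            np.add.at(counts, self.maps[g], 1.0)
        return theta0 / np.maximum(counts, 1.0)

    def fit(self, start=None, restarts=5, compute_se=True, gtol=1e-5, seed=0,
            se_method="observed"):
        theta0 = np.asarray(start, float) if start is not None else self._start()
        pos = self.positive
        n = self.n_total
        rng = np.random.default_rng(seed)

        def to_optim(raw):
            out = raw.copy()
            out[pos] = np.log(np.maximum(raw[pos], 1e-8))
            return out

        def from_optim(x):
            out = x.copy()
            out[pos] = np.exp(np.minimum(x[pos], 40.0))
            return out

        def objective(x):
            raw = from_optim(x)
            ll, g = self.loglik_grad(raw)
            if not np.isfinite(ll) or g is None:
                return 1e10, np.zeros_like(x)
            jac = np.ones_like(x)
            jac[pos] = np.exp(np.minimum(x[pos], 40.0))
            return -ll / n, -(g * jac) / n

        x0 = to_optim(theta0)
        best = _lbfgs_with_restarts(objective, x0, gtol, restarts, rng,
                                    options={"maxiter": 3000, "maxfun": 8000})
        _, gnorm, xhat = best
        converged = gnorm < gtol
        if not converged:
            warnings.warn(f"multigroup optimizer stopped with gradient norm {gnorm:.2e}",
                          ConvergenceWarning, stacklevel=2)
        theta = from_optim(xhat)
        ll, _ = self.loglik_grad(theta)
        ll_total = ll + sum(e.marginal_ll for e in self.engines.values())

        cov_joint = None
        se = np.full(self.n_joint, np.nan)
        if compute_se:
            H = self._information(theta, se_method)
            try:
                cov_joint = np.linalg.inv(H)
                d = np.diag(cov_joint)
                se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
            except np.linalg.LinAlgError:
                warnings.warn("observed information singular; no standard errors",
                              ConvergenceWarning, stacklevel=2)
        return MultigroupResults(self, theta, se, cov_joint, ll_total, ll,
                                 converged, gnorm)

    def _information(self, theta, se_method="expected", h=1e-5):
        """Joint information: groups are independent, so per-group
        information blocks scatter-add into the joint index space.
        Latent-moderator groups use the expected (Fisher) information of
        the exact Gaussian marginal when ``se_method == "expected"``;
        otherwise the negative Hessian."""
        I = np.zeros((self.n_joint, self.n_joint))
        for g in self.groups:
            eng = self.engines[g]
            th_g = theta[self.maps[g]]
            if eng.latent and se_method == "expected":
                Ig = eng.lmm._expected_information(
                    th_g, np.ones(th_g.size, dtype=bool))
            else:
                Ig = self._group_hessian(eng, th_g, h)
            I[np.ix_(self.maps[g], self.maps[g])] += Ig
        return I

    @staticmethod
    def _group_hessian(eng, theta, h=1e-5):
        m = theta.size
        H = np.zeros((m, m))
        for k in range(m):
            step = h * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += step
            tm[k] -= step
            _, gp = eng.loglik_grad(tp)
            _, gm = eng.loglik_grad(tm)
            if gp is None or gm is None:
                return np.full((m, m), np.nan)
            H[:, k] = -(gp - gm) / (2.0 * step)
        return 0.5 * (H + H.T)


class MultigroupResults:
    """Per-group structural estimates over a shared measurement model."""

    def __init__(self, model, theta, se, cov_joint, loglik_total,
                 loglik_conditional, converged, gradient_norm):
        self.model = model
        self.theta = theta
        self.joint_params = pd.Series(theta, index=model.joint_names)
        self.joint_se = pd.Series(se, index=model.joint_names)
        self.cov_joint = cov_joint
        self.loglik = loglik_total
        self.loglik_conditional = loglik_conditional
        self.converged = converged
        self.gradient_norm = gradient_norm
        self.groups = model.groups
        self.constraint_report = [
            f"{name} equal across groups" for name in model.shared_names]

    def group_params(self, group):
        m = self.model
        eng = m.engines[group]
        return pd.Series(self.theta[m.maps[group]], index=eng.names)

    def group_se(self, group):
        m = self.model
        return pd.Series(self.joint_se.to_numpy()[m.maps[group]],
                         index=m.engines[group].names)

    def group_loglik(self, group):
        """One group's casewise contribution evaluated at the joint solution."""
        m = self.model
        eng = m.engines[group]
        ll, _ = eng.loglik_grad(self.theta[m.maps[group]])
        return ll + eng.marginal_ll

    def interaction_coefficients(self, group):
        isp = self.model.ispec
        params = self.group_params(group)
        if isp.moderator_is_latent:
            return {o: float(params[isp.interaction_name(o)]) for o in isp.outcomes}
        lmm = self.model.engines[group].lmm
        return {o: float(params[f"{o}~{lmm._prod_col}"]) for o in isp.outcomes}

    def interaction_test(self, group, outcome):
        isp = self.model.ispec
        name = (isp.interaction_name(outcome) if isp.moderator_is_latent
                else f"{outcome}~{self.model.engines[group].lmm._prod_col}")
        b = float(self.group_params(group)[name])
        s = float(self.group_se(group)[name])
        z = b / s
        return {"b": b, "se": s, "z": z, "p": 2.0 * stats.norm.sf(abs(z))}

    def summary(self):
        lines = [
            "Multigroup latent-interaction model (known classes)",
            f"  groups: {', '.join(map(str, self.groups))};"
            f" shared measurement parameters: {len(self.model.shared_names)}",
            f"  total log-likelihood = {self.loglik:.3f}, converged: {self.converged}",
            "",
        ]
        for g in self.groups:
            for o in self.model.ispec.outcomes:
                t = self.interaction_test(g, o)
                lines.append(
                    f"  [{g}] interaction on {o}: b = {t['b']:.4f}"
                    f" (se {t['se']:.4f}, z = {t['z']:.2f}, p = {t['p']:.4f})")
        return "\n".join(lines)


def fit_multigroup_lms(ispec, table, group_var="group", equal_measurement=True,
                       **kwargs) -> MultigroupResults:
    fit_kwargs = {k: kwargs.pop(k) for k in list(kwargs)
                  if k in ("start", "restarts", "compute_se", "gtol", "seed")}
    model = MultigroupModerationModel(ispec, table, group_var=group_var,
                                      equal_measurement=equal_measurement, **kwargs)
    return model.fit(**fit_kwargs)
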