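"""Latent moderated structural equations (LMS).

Estimates models in which latent outcomes (e.g. executive function,
memory) are regressed on an observed predictor (lesion load), a
moderator, and their product. Two cases:

* **observed moderator** (a local-connectivity cluster z value): the
  product of the mean-centred predictor and moderator is a computed
  regressor and the model reduces exactly to a linear SEM;
* **latent moderator** (a network's global-connectivity factor): the
  product involves the latent, so the marginal likelihood integrates
  the moderator out by fixed-node Gauss-Hermite quadrature. Conditional
  on the moderator and the observed exogenous variables the system is
  linear-Gaussian, so each quadrature node contributes a Gaussian
  density with a node-shifted mean and a common covariance.

The latent moderator is scaled by a unit conditional (residual)
variance; by default it may regress on the predictor, which reproduces
the joint-Gaussian null model exactly when the interaction is absent.
Exogenous observed variables (predictor, covariates) are conditioned
on: rows missing them are dropped, and their saturated Gaussian
marginal is added to the reported log-likelihood so that likelihoods
are comparable with joint-model linear SEM fits. Missing indicator
entries are handled casewise, as in the linear engine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .cohort import as_subject_table
from .errors import ConvergenceWarning, SpecificationError
from .sem import (
    Param,
    PatternData,
    StructuralModel,
    _LOG2PI,
    _lbfgs_with_restarts,
)
from .spec import ModelSpec

__all__ = ["InteractionSpec", "LatentModerationModel", "ModerationResults",
           "fit_lms", "simple_slopes"]


@dataclass
class InteractionSpec:
    """Specification of one latent-moderation analysis.

    ``moderator`` may name a latent of ``base`` (>= 3 indicators) or an
    observed column; ``outcomes`` are latent names of ``base`` distinct
    from the moderator.
    """

    base: ModelSpec
    predictor: str
    moderator: str
    outcomes: tuple = ("ef",)
    quadrature_nodes: int = 16
    covariates: tuple = ()
    moderator_on_predictor: bool = True

    def __post_init__(self):
        self.outcomes = tuple(self.outcomes)
        self.covariates = tuple(self.covariates)
        if self.moderator in self.base.latents:
            n_ind = len(self.base.latents[self.moderator].indicators)
            if n_ind < 3:
                raise SpecificationError(
                    f"latent moderator {self.moderator!r} needs >= 3 indicators, has {n_ind}")
            if self.quadrature_nodes < 8:
                raise SpecificationError("need at least 8 quadrature nodes")
        for out in self.outcomes:
            if out not in self.base.latents:
                raise SpecificationError(f"outcome {out!r} is not a latent of the base model")
            if out == self.moderator:
                raise SpecificationError("outcomes must be distinct from the moderator")

    @property
    def moderator_is_latent(self):
        return self.moderator in self.base.latents

    def interaction_name(self, outcome):
        return f"{outcome}~{self.predictor}:{self.moderator}"


def _gh_nodes(k):
    x, w = np.polynomial.hermite.hermgauss(k)
    return x * math.sqrt(2.0), w / math.sqrt(math.pi)


# ---------------------------------------------------------------------------
# conditional (fixed-x) compiled structure for the latent-moderator case
# ---------------------------------------------------------------------------

class _CondModel:
    """Conditional linear system given the moderator and the fixed x's.

    Parameter kinds beyond the linear engine's 'A'/'S'/'a':

    * ``h``  — coefficient on the moderator (loading or structural),
    * ``g0`` — coefficient on the centred predictor,
    * ``gw`` — coefficient on predictor x moderator (the interaction),
    * ``gc`` — coefficient on covariate j (j stored in ``Param.j``),
    * ``gamma`` — regression of the moderator on the predictor,
    * ``kappa`` — moderator mean shift (used by multigroup fits).
    """

    def __init__(self, ispec: InteractionSpec, free_latent_means=False,
                 free_moderator_mean=False):
        base = ispec.base
        mod = ispec.moderator
        if base.identification_rule(mod) != "standardize_latent":
            raise SpecificationError(
                "the latent moderator must use standardize_latent identification")
        self.ispec = ispec
        self.obs = base.indicator_names()
        self.lats = [l for l in base.latents if l != mod]
        p, t = len(self.obs), len(self.obs) + len(self.lats)
        self.p, self.t = p, t
        idx = {v: k for k, v in enumerate(self.obs)}
        idx.update({v: p + k for k, v in enumerate(self.lats)})
        self.idx = idx
        self.A0 = np.zeros((t, t))
        self.S0 = np.zeros((t, t))
        self.a0 = np.zeros(t)
        self.params: list[Param] = []
        ap = self.params.append

        # measurement: non-moderator latents -> A; moderator loadings -> h
        for name, lat in base.latents.items():
            rule = base.identification_rule(name)
            for k, (ind, loading) in enumerate(lat.indicators):
                if name == mod:
                    ap(Param(f"{mod}=~{ind}", "h", idx[ind], 0))
                    continue
                i, j = idx[ind], idx[name]
                if loading != "free":
                    self.A0[i, j] = float(loading)
                elif rule == "fix_first_loading" and k == 0:
                    self.A0[i, j] = 1.0
                else:
                    ap(Param(f"{name}=~{ind}", "A", i, j))

        # base structural paths among retained variables
        for src, tgt in base.structural_equations():
            if src == mod:
                ap(Param(f"{tgt}~{src}", "h", idx[tgt], 0))
            else:
                ap(Param(f"{tgt}~{src}", "A", idx[tgt], idx[src]))

        # moderation structure
        for out in ispec.outcomes:
            ap(Param(f"{out}~{mod}", "h", idx[out], 0))
            ap(Param(f"{out}~{ispec.predictor}", "g0", idx[out], 0))
            ap(Param(ispec.interaction_name(out), "gw", idx[out], 0))
            for j, cov in enumerate(ispec.covariates):
                ap(Param(f"{out}~{cov}", "gc", idx[out], j))
        if ispec.moderator_on_predictor:
            ap(Param(f"{mod}~{ispec.predictor}", "gamma", 0, 0))
        if free_moderator_mean:
            ap(Param(f"{mod}~1", "kappa", 0, 0))

        # residual variances / covariances
        for v in self.obs:
            ap(Param(f"{v}~~{v}", "S", idx[v], idx[v], positive=True))
        for v1, v2 in base.residual_covariances:
            ap(Param(f"{v1}~~{v2}", "S", idx[v1], idx[v2]))

        # latent disturbances
        targets = {t_ for _, t_ in base.structural_equations()} | set(ispec.outcomes)
        for name in self.lats:
            rule = base.identification_rule(name)
            if rule == "standardize_latent":
                self.S0[idx[name], idx[name]] = 1.0
            else:
                ap(Param(f"{name}~~{name}", "S", idx[name], idx[name], positive=True))
        nonnested = [l for l in self.lats if base.latents[l].nested_under is None]
        endo = [l for l in nonnested if l in targets]
        exo = [l for l in nonnested if l not in targets]
        for grp in (endo, exo):
            for k, n1 in enumerate(grp):
                for n2 in grp[:k]:
                    ap(Param(f"{n1}~~{n2}", "S", idx[n1], idx[n2]))

        # intercepts
        for v in self.obs:
            ap(Param(f"{v}~1", "a", idx[v], 0))
        if free_latent_means:
            for out in ispec.outcomes:
                ap(Param(f"{out}~1", "a", idx[out], 0))

        self.names = [pr.name for pr in self.params]
        self.n_free = len(self.params)

    def build(self, theta):
        A, S, a = self.A0.copy(), self.S0.copy(), self.a0.copy()
        t, q = self.t, len(self.ispec.covariates)
        h, g0, gw = np.zeros(t), np.zeros(t), np.zeros(t)
        gc = np.zeros((t, q))
        gamma = 0.0
        kappa = 0.0
        for val, pr in zip(theta, self.params):
            if pr.kind == "A":
                A[pr.i, pr.j] = val
            elif pr.kind == "S":
                S[pr.i, pr.j] = S[pr.j, pr.i] = val
            elif pr.kind == "a":
                a[pr.i] = val
            elif pr.kind == "h":
                h[pr.i] = val
            elif pr.kind == "g0":
                g0[pr.i] = val
            elif pr.kind == "gw":
                gw[pr.i] = val
            elif pr.kind == "gc":
                gc[pr.i, pr.j] = val
            elif pr.kind == "gamma":
                gamma = val
            else:
                kappa = val
        return A, S, a, h, g0, gw, gc, gamma, kappa

    # optimizer-space transforms (log for positive parameters)
    def to_optim(self, theta):
        out = np.array(theta, dtype=float)
        for k, pr in enumerate(self.params):
            if pr.positive:
                out[k] = math.log(max(out[k], 1e-8))
        return out

    def from_optim(self, x):
        out = np.array(x, dtype=float)
        for k, pr in enumerate(self.params):
            if pr.positive:
                out[k] = math.exp(min(out[k], 40.0))
        return out

    def jac_optim(self, x):
        d = np.ones_like(x)
        for k, pr in enumerate(self.params):
            if pr.positive:
                d[k] = math.exp(min(x[k], 40.0))
        return d


class _LMSLoglik:
    """Quadrature marginal likelihood of one data block (one group).

    Two node layouts:

    * ``prior`` grid — classic Gauss-Hermite nodes on the moderator's
      N(0,1) disturbance, shifted by its regression on the predictor;
    * ``posterior`` grid (default, set via :meth:`set_grid`) — nodes
      placed at each subject's conditional posterior location and scale
      computed once at the starting values and then held fixed, so the
      likelihood stays smooth in the parameters while a small node
      count is already near-exact. The moderator's prior density then
      enters the integrand explicitly.
    """

    def __init__(self, cond: _CondModel, Y, w_centered, X_cov, nodes):
        self.cond = cond
        self.patterns = PatternData(Y)
        keep = ~np.isnan(Y).all(axis=1)
        self.w = w_centered[keep]
        self.X = X_cov[keep] if X_cov is not None else None
        self.n = self.patterns.n
        self.q_nodes, qw = _gh_nodes(nodes)
        self.logqw = np.log(qw)
        self.grid_M = None  # posterior-grid centers (n,)
        self.grid_S = None  # posterior-grid scales (n,)

    def _pieces(self, theta):
        cond = self.cond
        p, t = cond.p, cond.t
        A, S, a, h, g0, gw, gc, gamma, kappa = cond.build(theta)
        try:
            B = np.linalg.solve(np.eye(t) - A, np.eye(t))
        except np.linalg.LinAlgError:
            return None
        P = B[:p, :]
        Sigma = P @ S @ P.T
        n, w = self.n, self.w
        base = np.broadcast_to(P @ a, (n, p)).copy()
        base += np.outer(w, P @ g0)
        if self.X is not None and self.X.shape[1]:
            base += self.X @ (P @ gc).T
        dir_ = np.broadcast_to(P @ h, (n, p)).copy()
        dir_ += np.outer(w, P @ gw)
        return A, S, a, h, g0, gw, gc, gamma, kappa, B, P, Sigma, base, dir_

    def set_grid(self, theta, inflate=1.2):
        """Place the node grid at the per-subject posterior of the
        moderator evaluated at ``theta`` (usually the warm start)."""
        pieces = self._pieces(theta)
        if pieces is None:
            raise ValueError("non-invertible system at grid-placement values")
        A, S, a, h, g0, gw, gc, gamma, kappa, B, P, Sigma, base, dir_ = pieces
        M = np.empty(self.n)
        Sc = np.empty(self.n)
        mprior = kappa + gamma * self.w
        for (o, Yg), rows in zip(self.patterns.groups, self.patterns.row_groups):
            Sub = Sigma[np.ix_(o, o)]
            Si = np.linalg.inv(Sub)
            C = Yg - base[np.ix_(rows, o)]
            D = dir_[np.ix_(rows, o)]
            SiD = D @ Si
            tau = 1.0 + np.einsum("nk,nk->n", D, SiD)
            innov = np.einsum("nk,nk->n", SiD, C - mprior[rows, None] * D)
            M[rows] = mprior[rows] + innov / tau
            Sc[rows] = inflate / np.sqrt(tau)
        self.grid_M, self.grid_S = M, Sc

    def __call__(self, theta, want_grad=True):
        cond = self.cond
        p = cond.p
        pieces = self._pieces(theta)
        if pieces is None:
            return (-np.inf, None) if want_grad else -np.inf
        A, S, a, h, g0, gw, gc, gamma, kappa, B, P, Sigma, base, dir_ = pieces
        w, n = self.w, self.n
        posterior_grid = self.grid_M is not None
        mprior = kappa + gamma * w
        if posterior_grid:
            xi = self.grid_M[:, None] + self.grid_S[:, None] * self.q_nodes[None, :]
            # change of variables plus explicit N(xi; mprior, 1) density
            logw_ik = (self.logqw[None, :] + np.log(self.grid_S)[:, None]
                       + 0.5 * self.q_nodes[None, :] ** 2 + 0.5 * _LOG2PI
                       - 0.5 * (_LOG2PI + (xi - mprior[:, None]) ** 2))
        else:
            xi = mprior[:, None] + self.q_nodes[None, :]
            logw_ik = np.broadcast_to(self.logqw[None, :], (n, self.q_nodes.size))

        ll = 0.0
        if want_grad:
            G = np.zeros((p, p))
            V0 = np.zeros(p)
            V1 = np.zeros(p)
            Vw = np.zeros(p)
            V1w = np.zeros(p)
            Vc = np.zeros((p, self.X.shape[1])) if self.X is not None else None
            g_gamma = 0.0
            g_kappa = 0.0
        for (o, Yg), rows in zip(self.patterns.groups, self.patterns.row_groups):
            k_o = o.size
            Sub = Sigma[np.ix_(o, o)]
            try:
                cfac = np.linalg.cholesky(Sub)
            except np.linalg.LinAlgError:
                return (-np.inf, None) if want_grad else -np.inf
            logdet = 2.0 * np.log(np.diag(cfac)).sum()
            Si = np.linalg.inv(Sub)
            C = Yg - base[np.ix_(rows, o)]            # ng x k
            D = dir_[np.ix_(rows, o)]                 # ng x k
            xg = xi[rows]                             # ng x K
            R = C[:, None, :] - xg[:, :, None] * D[:, None, :]  # ng x K x k
            U = R @ Si
            quad = (R * U).sum(axis=2)
            logphi = -0.5 * (k_o * _LOG2PI + logdet + quad)
            logint = logphi + logw_ik[rows]
            li = logsumexp(logint, axis=1)
            ll += li.sum()
            if not want_grad:
                continue
            post = np.exp(logint - li[:, None])       # ng x K
            ng = Yg.shape[0]
            PU = post[:, :, None] * U                  # ng x K x k
            PUf = PU.reshape(-1, k_o)
            Uf = U.reshape(-1, k_o)
            G[np.ix_(o, o)] += 0.5 * (PUf.T @ Uf - ng * Si)
            wg = w[rows]
            V0[o] += PUf.sum(axis=0)
            V1[o] += (PU * xg[:, :, None]).sum(axis=(0, 1))
            Vw[o] += wg @ PU.sum(axis=1)
            V1w[o] += wg @ (PU * xg[:, :, None]).sum(axis=1)
            if Vc is not None and self.X.shape[1]:
                Vc[o, :] += PU.sum(axis=1).T @ self.X[rows]
            if posterior_grid:
                # gamma/kappa only enter the explicit prior density
                dev = post * (xg - mprior[rows, None])
                g_gamma += float(wg @ dev.sum(axis=1))
                g_kappa += float(dev.sum())
            else:
                # d xi / d gamma = w ; d xi / d kappa = 1 ; d mu / d xi = D
                PUD = (PU * D[:, None, :]).sum(axis=2)  # ng x K
                g_gamma += float(wg @ PUD.sum(axis=1))
                g_kappa += float(PUD.sum())
        if not want_grad:
            return ll
        if not np.isfinite(ll):
            return ll, None

        PGP = P.T @ G @ P
        M_ua = (np.outer(V0, a) + np.outer(V1, h) + np.outer(Vw, g0) + np.outer(V1w, gw))
        if Vc is not None and self.X is not None and self.X.shape[1]:
            M_ua += Vc @ gc.T
        dA = 2.0 * PGP @ S @ B.T + P.T @ M_ua @ B.T
        da = P.T @ V0
        dh = P.T @ V1
        dg0 = P.T @ Vw
        dgw = P.T @ V1w
        dgc = (P.T @ Vc) if Vc is not None else None
        grad = np.empty(cond.n_free)
        for k, pr in enumerate(cond.params):
            if pr.kind == "A":
                grad[k] = dA[pr.i, pr.j]
            elif pr.kind == "S":
                grad[k] = PGP[pr.i, pr.i] if pr.i == pr.j else 2.0 * PGP[pr.i, pr.j]
            elif pr.kind == "a":
                grad[k] = da[pr.i]
            elif pr.kind == "h":
                grad[k] = dh[pr.i]
            elif pr.kind == "g0":
                grad[k] = dg0[pr.i]
            elif pr.kind == "gw":
                grad[k] = dgw[pr.i]
            elif pr.kind == "gc":
                grad[k] = dgc[pr.i, pr.j]
            elif pr.kind == "gamma":
                grad[k] = g_gamma
            else:
                grad[k] = g_kappa
        return ll, grad


def _exogenous_marginal(Xblock):
    """Saturated Gaussian log-likelihood of the fixed-x block (complete
    rows) and its free-moment count; keeps conditional fits comparable
    with joint-model linear SEM likelihoods."""
    X = np.asarray(Xblock, dtype=float)
    n, q = X.shape
    if q == 0:
        return 0.0, 0
    mu = X.mean(axis=0)
    Sg = np.cov(X.T, ddof=0).reshape(q, q)
    sign, logdet = np.linalg.slogdet(Sg)
    ll = -0.5 * n * (q * _LOG2PI + logdet + q)
    return float(ll), q + q * (q + 1) // 2


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class LatentModerationModel:
    """Interaction of an observed predictor with a latent or observed
    moderator on latent outcomes; statsmodels-style ``fit`` interface."""

    def __init__(self, ispec: InteractionSpec, table, free_latent_means=False,
                 free_moderator_mean=False, grid="posterior"):
        self.ispec = ispec
        self.table = as_subject_table(table)
        if grid not in ("posterior", "prior"):
            raise SpecificationError("grid must be 'posterior' or 'prior'")
        self._grid = grid
        cols = self.table.data.columns
        for v in (ispec.predictor, *ispec.covariates):
            if v not in cols:
                raise SpecificationError(f"observed variable {v!r} not in table")
        if not ispec.moderator_is_latent and ispec.moderator not in cols:
            raise SpecificationError(f"observed moderator {ispec.moderator!r} not in table")
        self._free_latent_means = free_latent_means
        self._free_moderator_mean = free_moderator_mean
        if ispec.moderator_is_latent:
            self._setup_latent()
        else:
            self._setup_observed()

    # -- observed moderator: exact reduction to a linear SEM ---------
    def _setup_observed(self):
        isp = self.ispec
        data = self.table.data.copy()
        wc = data[isp.predictor] - data[isp.predictor].mean()
        mc = data[isp.moderator] - data[isp.moderator].mean()
        self._prod_col = f"{isp.predictor}_x_{isp.moderator}"
        self._pred_c, self._mod_c = f"{isp.predictor}_c", f"{isp.moderator}_c"
        data[self._pred_c] = wc
        data[self._mod_c] = mc
        data[self._prod_col] = wc * mc
        paths = []
        for out in isp.outcomes:
            paths += [(self._pred_c, out), (self._mod_c, out), (self._prod_col, out)]
            paths += [(cov, out) for cov in isp.covariates]
        self._linear_spec = isp.base.with_paths(paths)
        self._linear_model = StructuralModel(self._linear_spec, data)
        self.moderator_sd = float(mc.std(ddof=0))
        self.n_effective = self._linear_model.n_effective

    # -- latent moderator: quadrature machinery ----------------------
    def _setup_latent(self):
        isp = self.ispec
        data = self.table.data
        fixed_cols = [isp.predictor, *isp.covariates]
        ok = ~data[fixed_cols].isna().any(axis=1)
        self.n_dropped_fixed = int((~ok).sum())
        data = data.loc[ok]
        self.cond = _CondModel(isp, self._free_latent_means, self._free_moderator_mean)
        Y = data[self.cond.obs].to_numpy(dtype=float)
        w = data[isp.predictor].to_numpy(dtype=float)
        self._w_mean = w.mean()
        wc = w - self._w_mean
        X = None
        if isp.covariates:
            X = data[list(isp.covariates)].to_numpy(dtype=float)
            X = X - X.mean(axis=0)
        self._Xblock = np.column_stack([wc] + ([X[:, j] for j in range(X.shape[1])] if X is not None else []))
        self.loglik_obj = _LMSLoglik(self.cond, Y, wc, X, isp.quadrature_nodes)
        self.n_effective = self.loglik_obj.n
        self._ll_marg, self._marg_free = _exogenous_marginal(self._Xblock)
        self.predictor_sd = float(wc.std(ddof=0))

    def _start_from_linear(self):
        """Warm start: the no-interaction linear SEM solution."""
        isp = self.ispec
        data = self.table.data.copy()
        data[f"{isp.predictor}__c"] = data[isp.predictor] - data[isp.predictor].mean()
        pred = f"{isp.predictor}__c"
        paths = []
        for out in isp.outcomes:
            paths += [(pred, out), (isp.moderator, out)]
            paths += [(cov, out) for cov in isp.covariates]
        lin = StructuralModel(isp.base.with_paths(paths), data)
        lin_res = lin.fit(compute_se=False, restarts=2)
        est = lin_res.params
        theta = np.zeros(self.cond.n_free)
        var_w = est.get(f"{pred}~~{pred}", np.nanvar(data[pred]))
        for k, pr in enumerate(self.cond.params):
            name = pr.name
            if pr.kind == "gw" or pr.kind == "kappa":
                theta[k] = 0.0
            elif pr.kind == "gamma":
                cov_wm = est.get(f"{pred}~~{isp.moderator}", 0.0)
                theta[k] = cov_wm / max(var_w, 1e-8)
            elif pr.kind == "g0":
                out = self.cond.lats[pr.i - self.cond.p]
                theta[k] = est.get(f"{out}~{pred}", 0.0)
            elif pr.kind == "gc":
                out = self.cond.lats[pr.i - self.cond.p]
                theta[k] = est.get(f"{out}~{isp.covariates[pr.j]}", 0.0)
            elif name in est.index:
                theta[k] = est[name]
            elif pr.kind == "S" and pr.i == pr.j:
                theta[k] = 1.0
        self._linear_warm = lin_res
        return theta

    # -- fitting -----------------------------------------------------
    def fit(self, start=None, restarts=5, compute_se=True, gtol=1e-5, seed=0,
            fixed=None, se_method="observed", check_quadrature=False):
        """Maximize the (marginal) likelihood; returns ModerationResults.

        ``fixed`` optionally maps parameter names to values held fixed
        during optimization (used for nested no-interaction fits).
        ``se_method`` selects the information matrix for standard
        errors: ``"observed"`` (negative Hessian at the optimum,
        default) or ``"expected"`` (Fisher information of the exact
        Gaussian marginal given the observed predictor).
        """
        isp = self.ispec
        if not isp.moderator_is_latent:
            res = self._linear_model.fit(start=start, restarts=restarts,
                                         compute_se=compute_se, gtol=gtol, seed=seed)
            return ModerationResults(self, res.params, res.se, res.cov_params,
                                     res.loglik, res.converged, res.gradient_norm,
                                     linear_results=res)

        cond = self.cond
        theta0 = np.asarray(start, float) if start is not None else self._start_from_linear()
        if self._grid == "posterior":
            self.loglik_obj.set_grid(theta0)
        fixed_idx = {}
        if fixed:
            for name, val in fixed.items():
                fixed_idx[cond.names.index(name)] = float(val)
        free_mask = np.array([k not in fixed_idx for k in range(cond.n_free)])

        def full_theta(x_free_raw):
            th = np.empty(cond.n_free)
            th[free_mask] = x_free_raw
            for k, v in fixed_idx.items():
                th[k] = v
            return th

        n = self.n_effective
        rng = np.random.default_rng(seed)

        def objective(x):
            raw_free = from_optim_free(x)
            th = full_theta(raw_free)
            ll, g = self.loglik_obj(th)
            if not np.isfinite(ll) or g is None:
                return 1e10, np.zeros_like(x)
            return -ll / n, -(g[free_mask] * jac_free(x)) / n

        pos_free = np.array([pr.positive for pr in cond.params])[free_mask]

        def to_optim_free(raw):
            out = raw.copy()
            out[pos_free] = np.log(np.maximum(raw[pos_free], 1e-8))
            return out

        def from_optim_free(x):
            out = x.copy()
            out[pos_free] = np.exp(np.minimum(x[pos_free], 40.0))
            return out

        def jac_free(x):
            d = np.ones_like(x)
            d[pos_free] = np.exp(np.minimum(x[pos_free], 40.0))
            return d

        x0 = to_optim_free(theta0[free_mask])
        best = _lbfgs_with_restarts(objective, x0, gtol, restarts, rng)
        _, gnorm, xhat = best
        converged = gnorm < gtol
        if not converged:
            warnings.warn(f"LMS optimizer stopped with gradient norm {gnorm:.2e}",
                          ConvergenceWarning, stacklevel=2)
        theta = full_theta(from_optim_free(xhat))
        ll = self.loglik_obj(theta, want_grad=False) + self._ll_marg

        se = np.full(cond.n_free, np.nan)
        cov_params = None
        if compute_se:
            if se_method == "expected":
                H = self._expected_information(theta, free_mask)
            else:
                H = self._observed_information(theta, free_mask)
            try:
                cov_free = np.linalg.inv(H)
                cov_params = np.full((cond.n_free, cond.n_free), np.nan)
                ix = np.flatnonzero(free_mask)
                cov_params[np.ix_(ix, ix)] = cov_free
                d = np.diag(cov_free)
                se[ix] = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
            except np.linalg.LinAlgError:
                warnings.warn("observed information singular; no standard errors",
                              ConvergenceWarning, stacklevel=2)
        names = cond.names
        result = ModerationResults(self, pd.Series(theta, index=names),
                                   pd.Series(se, index=names), cov_params,
                                   ll, converged, gnorm)
        if check_quadrature:
            shift = self.quadrature_shift(result)
            if shift > 1e-3:
                warnings.warn(
                    f"quadrature under-resolved: interaction estimate shifts "
                    f"{shift:.2e} when nodes double", ConvergenceWarning,
                    stacklevel=2)
        return result

    def _conditional_moments(self, theta):
        """Per-subject implied mean and rank-one covariance pieces of
        the exact Gaussian marginal given the fixed x's: ``mu_i`` and
        ``Sigma_i = Sigma + dir_i dir_i'``."""
        cond = self.cond
        obj = self.loglik_obj
        p = cond.p
        A, S, a, h, g0, gw, gc, gamma, kappa = cond.build(theta)
        B = np.linalg.solve(np.eye(cond.t) - A, np.eye(cond.t))
        P = B[:p]
        Sigma = P @ S @ P.T
        w = obj.w
        base = (P @ a)[None, :] + np.outer(w, P @ g0)
        if obj.X is not None and obj.X.shape[1]:
            base = base + obj.X @ (P @ gc).T
        dir_ = (P @ h)[None, :] + np.outer(w, P @ gw)
        mprior = kappa + gamma * w
        mu = base + mprior[:, None] * dir_
        SigI = Sigma[None, :, :] + dir_[:, :, None] * dir_[:, None, :]
        return mu, SigI

    def _expected_information(self, theta, free_mask, h=1e-6):
        """Fisher information of the exact Gaussian marginal, assembled
        from central differences of the per-subject moment maps.

        Exact for one latent moderator entering linearly given the
        observed predictor — precisely the model class fitted here.
        """
        ix = np.flatnonzero(free_mask)
        m = ix.size
        obj = self.loglik_obj
        n, p = obj.n, self.cond.p
        Dmu = np.empty((m, n, p))
        DSig = np.empty((m, n, p, p))
        for col, k in enumerate(ix):
            step = h * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += step
            tm[k] -= step
            mup, Sp = self._conditional_moments(tp)
            mum, Sm = self._conditional_moments(tm)
            Dmu[col] = (mup - mum) / (2.0 * step)
            DSig[col] = (Sp - Sm) / (2.0 * step)
        _, Sig0 = self._conditional_moments(theta)
        I = np.zeros((m, m))
        for (o, _), rows in zip(obj.patterns.groups, obj.patterns.row_groups):
            sub = np.ix_(rows, o, o)
            Sinv = np.linalg.inv(Sig0[sub])
            dmu = Dmu[np.ix_(np.arange(m), rows, o)]
            dsig = DSig[np.ix_(np.arange(m), rows, o, o)]
            Wm = np.einsum("npq,jnq->jnp", Sinv, dmu)
            I += np.einsum("jnp,knp->jk", dmu, Wm)
            T = np.einsum("npq,jnqr->jnpr", Sinv, dsig)
            I += 0.5 * np.einsum("jnpq,knqp->jk", T, T)
        return 0.5 * (I + I.T)

    def _observed_information(self, theta, free_mask, h=1e-5):
        ix = np.flatnonzero(free_mask)
        m = ix.size
        H = np.zeros((m, m))
        for col, k in enumerate(ix):
            step = h * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += step
            tm[k] -= step
            _, gp = self.loglik_obj(tp)
            _, gm = self.loglik_obj(tm)
            if gp is None or gm is None:
                return np.full((m, m), np.nan)
            H[:, col] = -(gp[ix] - gm[ix]) / (2.0 * step)
        return 0.5 * (H + H.T)

    def quadrature_shift(self, result, factor=2):
        """Refit with ``factor`` x the quadrature nodes from the current
        solution; returns the largest absolute change among the
        interaction coefficients (under-resolution diagnostic)."""
        isp = self.ispec
        if not isp.moderator_is_latent:
            return 0.0
        dense = InteractionSpec(base=isp.base, predictor=isp.predictor,
                                moderator=isp.moderator, outcomes=isp.outcomes,
                                quadrature_nodes=isp.quadrature_nodes * factor,
                                covariates=isp.covariates,
                                moderator_on_predictor=isp.moderator_on_predictor)
        model = LatentModerationModel(dense, self.table,
                                      self._free_latent_means, self._free_moderator_mean,
                                      grid=self._grid)
        res = model.fit(start=result.params.to_numpy(), compute_se=False, restarts=1)
        shifts = [abs(res.interaction_coefficients[o] - result.interaction_coefficients[o])
                  for o in isp.outcomes]
        return max(shifts)


class ModerationResults:
    """Interaction fit: coefficients, Wald tests, simple slopes."""

    def __init__(self, model, params, se, cov_params, loglik, converged,
                 gradient_norm, linear_results=None):
        self.model = model
        self.ispec = model.ispec
        self.params = params
        self.se = se
        self.cov_params = cov_params
        self.loglik = loglik
        self.converged = converged
        self.gradient_norm = gradient_norm
        self.linear_results = linear_results
        self.n_effective = model.n_effective

    # -- naming ------------------------------------------------------
    def _pname(self, outcome, which):
        isp = self.ispec
        if isp.moderator_is_latent:
            return {"interaction": isp.interaction_name(outcome),
                    "predictor": f"{outcome}~{isp.predictor}",
                    "moderator": f"{outcome}~{isp.moderator}"}[which]
        m = self.model
        return {"interaction": f"{outcome}~{m._prod_col}",
                "predictor": f"{outcome}~{m._pred_c}",
                "moderator": f"{outcome}~{m._mod_c}"}[which]

    @property
    def interaction_coefficients(self):
        return {o: float(self.params[self._pname(o, "interaction")])
                for o in self.ispec.outcomes}

    @property
    def main_effects(self):
        out = {}
        for o in self.ispec.outcomes:
            out[(self.ispec.predictor, o)] = float(self.params[self._pname(o, "predictor")])
            out[(self.ispec.moderator, o)] = float(self.params[self._pname(o, "moderator")])
        return out

    def interaction_test(self, outcome):
        """Wald z test of the interaction coefficient for one outcome."""
        name = self._pname(outcome, "interaction")
        b, s = float(self.params[name]), float(self.se[name])
        z = b / s
        return {"b": b, "se": s, "z": z, "p": 2.0 * stats.norm.sf(abs(z))}

    @property
    def moderator_sd(self):
        """Model-implied SD of the moderator."""
        isp = self.ispec
        if not isp.moderator_is_latent:
            return self.model.moderator_sd
        gamma = float(self.params.get(f"{isp.moderator}~{isp.predictor}", 0.0))
        return math.sqrt(1.0 + gamma**2 * self.model.predictor_sd**2)

    # -- simple slopes ----------------------------------------------
    def slope_table(self, outcome=None, levels=(-1.0, 1.0)):
        """Conditional slopes of the outcome on the predictor at fixed
        moderator levels (in moderator-SD units).

        By construction ``slope = b_predictor + b_interaction * level * SD``.
        """
        outs = self.ispec.outcomes if outcome is None else (outcome,)
        rows = []
        for o in outs:
            if o not in self.ispec.outcomes:
                raise SpecificationError(f"unknown outcome {o!r}")
            bp = float(self.params[self._pname(o, "predictor")])
            bi = float(self.params[self._pname(o, "interaction")])
            sd = self.moderator_sd
            for lv in levels:
                slope = bp + bi * lv * sd
                var = self._slope_var(o, lv * sd)
                rows.append({"outcome": o, "moderator_level": lv, "slope": slope,
                             "se": math.sqrt(var) if var == var and var >= 0 else math.nan})
        return pd.DataFrame(rows)

    def _slope_var(self, outcome, level_abs):
        if self.cov_params is None:
            return math.nan
        names = self.params.index.tolist()
        i = names.index(self._pname(outcome, "predictor"))
        j = names.index(self._pname(outcome, "interaction"))
        C = self.cov_params
        return float(C[i, i] + level_abs**2 * C[j, j] + 2.0 * level_abs * C[i, j])

    def prediction_table(self, outcome, levels=(-1.0, 1.0), n_grid=50, ci=0.80):
        """Centered predicted outcome over the observed predictor range
        at low/high moderator, with confidence bands; tidy long format
        suitable for line plots."""
        isp = self.ispec
        data = self.model.table.data
        w = data[isp.predictor].dropna().to_numpy(dtype=float)
        grid = np.linspace(w.min(), w.max(), n_grid) - w.mean()
        bm = float(self.params[self._pname(outcome, "moderator")])
        zq = stats.norm.ppf(0.5 + ci / 2.0)
        frames = []
        for lv in levels:
            L = lv * self.moderator_sd
            bp = float(self.params[self._pname(outcome, "predictor")])
            bi = float(self.params[self._pname(outcome, "interaction")])
            pred = bp * grid + bm * L + bi * grid * L
            sv = self._slope_var(outcome, L)
            band = zq * np.sqrt(np.maximum(sv, 0.0)) * np.abs(grid) if sv == sv else np.nan
            frames.append(pd.DataFrame({
                "outcome": outcome, "moderator_level": lv,
                "predictor_centered": grid, "predicted": pred,
                "lower": pred - band, "upper": pred + band,
            }))
        return pd.concat(frames, ignore_index=True)

    def plot_simple_slopes(self, outcome, ax=None, levels=(-1.0, 1.0)):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.prediction_table(outcome, levels=levels)
        for lv, sub in tab.groupby("moderator_level"):
            label = f"{'+' if lv > 0 else ''}{lv:g} SD {self.ispec.moderator}"
            ax.plot(sub.predictor_centered, sub.predicted, label=label)
            ax.fill_between(sub.predictor_centered, sub.lower, sub.upper, alpha=0.2)
        ax.set_xlabel(f"{self.ispec.predictor} (centered)")
        ax.set_ylabel(f"predicted {outcome} (centered)")
        ax.legend()
        return ax

    def summary(self):
        lines = [
            "Latent moderated structural equations"
            if self.ispec.moderator_is_latent else
            "Observed-moderator interaction model (linear SEM reduction)",
            f"  predictor: {self.ispec.predictor}, moderator: {self.ispec.moderator}"
            f" ({'latent' if self.ispec.moderator_is_latent else 'observed'})",
            f"  n = {self.n_effective}, log-likelihood = {self.loglik:.3f},"
            f" converged: {self.converged}",
            "",
        ]
        for o in self.ispec.outcomes:
            t = self.interaction_test(o)
            lines.append(
                f"  interaction on {o}: b = {t['b']:.4f} (se {t['se']:.4f},"
                f" z = {t['z']:.2f}, p = {t['p']:.4f})")
        st = self.slope_table()
        lines.append("")
        for _, r in st.iterrows():
            lines.append(
                f"  slope of {r.outcome} on {self.ispec.predictor} at "
                f"{'+' if r.moderator_level > 0 else ''}{r.moderator_level:g} SD: "
                f"{r.slope:.4f} (se {r.se:.4f})")
        return "\n".join(lines)


def fit_lms(ispec_or_base, table, predictor=None, moderator=None, outcomes=None,
            **kwargs) -> ModerationResults:
    """Fit a latent-moderation model.

    Either pass a ready :class:`InteractionSpec`, or a base
    :class:`ModelSpec` plus ``predictor``/``moderator``/``outcomes``.
    """
    if isinstance(ispec_or_base, InteractionSpec):
        isp = ispec_or_base
    else:
        isp = InteractionSpec(base=ispec_or_base, predictor=predictor,
                              moderator=moderator, outcomes=tuple(outcomes))
    fit_kwargs = {k: kwargs.pop(k) for k in list(kwargs)
                  if k in ("start", "restarts", "compute_se", "gtol", "seed", "fixed")}
    model = LatentModerationModel(isp, table, **kwargs)
    return model.fit(**fit_kwargs)


def simple_slopes(result: ModerationResults, outcome: str, levels=(-1.0, 1.0)):
    """Slope/prediction table at the given moderator levels (SD units)."""
    return {
        "slopes": result.slope_table(outcome, levels=levels),
        "predictions": result.prediction_table(outcome, levels=levels),
    }
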