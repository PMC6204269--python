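"""Linear structural-equation core with full-information maximum likelihood.

The model is held in reticular-action form: with ``v`` stacking the
observed variables and the latents, ``v = a + A v + u``, ``u ~ N(0, S)``,
so the implied moments of the observed block are ``mu = F (I-A)^{-1} a``
and ``Sigma = F (I-A)^{-1} S (I-A)^{-T} F'`` with ``F`` the selection of
the observed rows.

Missing data are handled casewise (FIML): subjects are grouped by
missingness pattern and each group contributes the Gaussian log-density
of its observed subvector. The chi-square statistic compares the fitted
model with the saturated model, itself estimated under the same
missingness handling (EM on means and covariances). Identification
follows the per-latent rule of the :class:`~lesionsem.spec.ModelSpec`:
``standardize_latent`` fixes the latent (residual, if endogenous)
variance to 1; ``fix_first_loading`` fixes the first loading to 1.

Optimization is quasi-Newton (L-BFGS) on a log-transformed
parameterization that keeps variances positive, with random restarts on
failure; standard errors come from the observed information matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .cohort import as_subject_table
from .errors import ConvergenceWarning, SpecificationError
from .indices import chi2_difference, fit_indices
from .spec import FREE, ModelSpec

__all__ = [
    "StructuralModel",
    "SEMResults",
    "fit_sem",
    "fiml_loglik",
    "saturated_moments",
    "chi2_difference",
]

_LOG2PI = math.log(2.0 * math.pi)


def _lbfgs_with_restarts(objective, x0, gtol, restarts, rng,
                         options=None):
    """L-BFGS with a polish pass and jittered restarts.

    Attempt 0 starts at ``x0``; attempt 1 polishes from the best point
    found (L-BFGS often stops on the relative-f criterion just short of
    the gradient tolerance); later attempts jitter the start. Returns
    ``(fun, gnorm, x)`` for the best point.
    """
    opts = {"maxiter": 2000, "maxfun": 5000, "ftol": 1e-13, "gtol": 1e-8}
    if options:
        opts.update(options)
    best = None
    for attempt in range(max(1, restarts)):
        if attempt == 0:
            xs = x0
        elif attempt == 1:
            xs = best[2]
        else:
            xs = x0 + 0.1 * rng.standard_normal(x0.size)
        res = optimize.minimize(objective, xs, jac=True, method="L-BFGS-B",
                                options=opts)
        gnorm = float(np.max(np.abs(res.jac)))
        cand = (res.fun, gnorm, res.x)
        if best is None or cand[0] < best[0] - 1e-12:
            best = cand
        if gnorm < gtol:
            best = cand
            break
    return best


# ---------------------------------------------------------------------------
# compiled parameter structure
# ---------------------------------------------------------------------------

@dataclass
class Param:
    name: str
    kind: str  # 'A' | 'S' | 'a'
    i: int
    j: int
    positive: bool = False


@dataclass
class CompiledModel:
    """Index structure mapping a free-parameter vector onto (A, S, a)."""

    spec: ModelSpec
    obs: list
    lats: list
    A0: np.ndarray
    S0: np.ndarray
    a0: np.ndarray
    params: list = field(default_factory=list)

    @property
    def p(self):
        return len(self.obs)

    @property
    def t(self):
        return len(self.obs) + len(self.lats)

    @property
    def n_free(self):
        return len(self.params)

    @property
    def names(self):
        return [pr.name for pr in self.params]

    def build(self, theta):
        """Raw parameter vector -> (A, S, a) matrices."""
        A = self.A0.copy()
        S = self.S0.copy()
        a = self.a0.copy()
        for val, pr in zip(theta, self.params):
            if pr.kind == "A":
                A[pr.i, pr.j] = val
            elif pr.kind == "S":
                S[pr.i, pr.j] = val
                S[pr.j, pr.i] = val
            else:
                a[pr.i] = val
        return A, S, a

    def to_optim(self, theta):
        """Raw -> optimizer space (log for positive parameters)."""
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
        """d raw / d optimizer coordinate (diagonal)."""
        d = np.ones_like(x)
        for k, pr in enumerate(self.params):
            if pr.positive:
                d[k] = math.exp(min(x[k], 40.0))
        return d


def compile_model(spec: ModelSpec) -> CompiledModel:
    obs = spec.observed_names()
    lats = list(spec.latents)
    overlap = set(obs) & set(lats)
    if overlap:
        raise SpecificationError(f"names used as both observed and latent: {sorted(overlap)}")
    t = len(obs) + len(lats)
    idx = {v: k for k, v in enumerate(obs)}
    idx.update({v: len(obs) + k for k, v in enumerate(lats)})

    A0 = np.zeros((t, t))
    S0 = np.zeros((t, t))
    a0 = np.zeros(t)
    cm = CompiledModel(spec=spec, obs=obs, lats=lats, A0=A0, S0=S0, a0=a0)

    eqs = spec.structural_equations()
    latent_targets = {tgt for _, tgt in eqs if tgt in spec.latents}
    obs_targets = {tgt for _, tgt in eqs if tgt not in spec.latents}
    indicators = spec.indicator_names()
    exo_obs = [v for v in obs if v not in indicators and v not in obs_targets]

    # measurement block
    for lat in spec.latents.values():
        rule = spec.identification_rule(lat.name)
        for k, (ind, loading) in enumerate(lat.indicators):
            i, j = idx[ind], idx[lat.name]
            if loading != FREE:
                A0[i, j] = float(loading)
            elif rule == "fix_first_loading" and k == 0:
                A0[i, j] = 1.0
            else:
                cm.params.append(Param(f"{lat.name}=~{ind}", "A", i, j))

    # structural block (includes covariate paths)
    for src, tgt in eqs:
        if src not in idx or tgt not in idx:
            missing = [v for v in (src, tgt) if v not in idx]
            raise SpecificationError(f"path references unknown variables: {missing}")
        cm.params.append(Param(f"{tgt}~{src}", "A", idx[tgt], idx[src]))

    # indicator residual variances, observed-target disturbances
    for v in indicators:
        cm.params.append(Param(f"{v}~~{v}", "S", idx[v], idx[v], positive=True))
    for v in obs_targets:
        if v not in indicators:
            cm.params.append(Param(f"{v}~~{v}", "S", idx[v], idx[v], positive=True))
    for v1, v2 in spec.residual_covariances:
        cm.params.append(Param(f"{v1}~~{v2}", "S", idx[v1], idx[v2]))

    # exogenous observed block: free moments, saturated within the block
    # and against the exogenous (non-nested) latents
    exo_lats = [name for name in lats
                if name not in latent_targets and spec.latents[name].nested_under is None]
    for k, v in enumerate(exo_obs):
        cm.params.append(Param(f"{v}~~{v}", "S", idx[v], idx[v], positive=True))
        for w in exo_obs[:k]:
            cm.params.append(Param(f"{v}~~{w}", "S", idx[v], idx[w]))
        for name in exo_lats:
            cm.params.append(Param(f"{v}~~{name}", "S", idx[v], idx[name]))

    # latent variances / disturbances
    for name in lats:
        lat = spec.latents[name]
        rule = spec.identification_rule(name)
        if rule == "standardize_latent":
            S0[idx[name], idx[name]] = 1.0
        else:
            cm.params.append(Param(f"{name}~~{name}", "S", idx[name], idx[name], positive=True))
    # covariances among exogenous non-nested latents; nested latents stay
    # orthogonal to everything, disturbances of endogenous non-nested
    # latents are free to covary
    for k, n1 in enumerate(exo_lats):
        for n2 in exo_lats[:k]:
            cm.params.append(Param(f"{n1}~~{n2}", "S", idx[n1], idx[n2]))
    endo_free = [name for name in lats
                 if name in latent_targets and spec.latents[name].nested_under is None]
    for k, n1 in enumerate(endo_free):
        for n2 in endo_free[:k]:
            cm.params.append(Param(f"{n1}~~{n2}", "S", idx[n1], idx[n2]))

    # observed intercepts; latent means fixed to zero
    for v in obs:
        cm.params.append(Param(f"{v}~1", "a", idx[v], 0))

    return cm


def start_values(cm: CompiledModel, Y: np.ndarray) -> np.ndarray:
    """Moment-based starting values (raw scale)."""
    means = np.nanmean(Y, axis=0)
    sds = np.nanstd(Y, axis=0, ddof=0)
    sds = np.where(sds > 0, sds, 1.0)
    obs_idx = {v: k for k, v in enumerate(cm.obs)}
    spec = cm.spec

    # per-latent reference indicator for loading signs
    ref = {}
    for name, lat in spec.latents.items():
        if lat.indicators:
            ref[name] = lat.indicators[0][0]

    def paircov(u, v):
        cols = Y[:, [obs_idx[u], obs_idx[v]]]
        ok = ~np.isnan(cols).any(axis=1)
        if ok.sum() < 3:
            return 0.0
        c = np.cov(cols[ok].T, ddof=0)
        return float(c[0, 1])

    theta = np.empty(cm.n_free)
    for k, pr in enumerate(cm.params):
        if pr.kind == "a":
            theta[k] = means[pr.i] if pr.i < cm.p else 0.0
        elif pr.kind == "S":
            if pr.i != pr.j:
                theta[k] = 0.0
            elif pr.i < cm.p:
                v = cm.obs[pr.i]
                full = sds[pr.i] ** 2
                theta[k] = full if v not in spec.indicator_names() else 0.5 * full
            else:
                theta[k] = 1.0
        else:  # A entry
            tgt = cm.obs[pr.i] if pr.i < cm.p else cm.lats[pr.i - cm.p]
            src = cm.obs[pr.j] if pr.j < cm.p else cm.lats[pr.j - cm.p]
            if src in spec.latents and tgt in obs_idx:  # loading
                lat = spec.latents[src]
                nested = lat.nested_under is not None
                scale = 0.3 if nested else 0.7
                r = ref[src]
                if tgt == r or nested:
                    theta[k] = scale * sds[obs_idx[tgt]]
                else:
                    c = paircov(tgt, r)
                    theta[k] = c / max(0.7 * sds[obs_idx[r]], 1e-3)
                    if theta[k] == 0.0:
                        theta[k] = 0.3 * sds[obs_idx[tgt]]
            else:  # regression path
                theta[k] = 0.0
    return theta


# ---------------------------------------------------------------------------
# casewise Gaussian likelihood machinery
# ---------------------------------------------------------------------------

class PatternData:
    """Rows grouped by missingness pattern over the modeled columns."""

    def __init__(self, Y: np.ndarray):
        Y = np.asarray(Y, dtype=float)
        keep = ~np.isnan(Y).all(axis=1)
        self.n_dropped = int((~keep).sum())
        Y = Y[keep]
        if Y.shape[0] == 0:
            raise SpecificationError("no rows with any observed modeled variable")
        never = np.isnan(Y).all(axis=0)
        if never.any():
            raise SpecificationError(
                f"modeled variables never observed at column indices {np.where(never)[0]}")
        self.Y = Y
        self.n, self.p = Y.shape
        mask = ~np.isnan(Y)
        self.complete = bool(mask.all())
        pats, inv = np.unique(mask, axis=0, return_inverse=True)
        self.groups = []
        self.row_groups = []
        for g in range(pats.shape[0]):
            rows = np.flatnonzero(inv == g)
            o = np.flatnonzero(pats[g])
            self.groups.append((o, Y[np.ix_(rows, o)]))
            self.row_groups.append(rows)


def _gaussian_ll_grad(mu, Sigma, patterns: PatternData, want_grad=True):
    """Casewise Gaussian log-likelihood and moment-space gradients.

    Returns ``(ll, G, gmu)`` with ``G = dll/dSigma`` (full-matrix
    convention, symmetric) and ``gmu = dll/dmu`` scattered to size p.
    """
    p = patterns.p
    ll = 0.0
    G = np.zeros((p, p)) if want_grad else None
    gmu = np.zeros(p) if want_grad else None
    for o, Yg in patterns.groups:
        k = o.size
        Sub = Sigma[np.ix_(o, o)]
        try:
            c, low = linalg.cho_factor(Sub, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return -np.inf, None, None
        logdet = 2.0 * np.log(np.diag(c)).sum()
        R = Yg - mu[o]
        SiR = linalg.cho_solve((c, low), R.T, check_finite=False).T
        quad = float(np.einsum("ij,ij->", R, SiR))
        ng = Yg.shape[0]
        ll += -0.5 * (ng * (k * _LOG2PI + logdet) + quad)
        if want_grad:
            Si = linalg.cho_solve((c, low), np.eye(k), check_finite=False)
            W = SiR.T @ SiR
            Go = 0.5 * (W - ng * Si)
            G[np.ix_(o, o)] += Go
            gmu[o] += SiR.sum(axis=0)
    return ll, G, gmu


def fiml_loglik(Y, mean, cov):
    """Casewise (FIML) Gaussian log-likelihood of ``Y`` given moments.

    ``Y`` may be a DataFrame or array with NaN marking missing entries;
    each row contributes the log-density of its observed subvector.
    """
    Y = np.asarray(Y, dtype=float)
    patterns = PatternData(Y)
    ll, _, _ = _gaussian_ll_grad(np.asarray(mean, float), np.asarray(cov, float),
                                 patterns, want_grad=False)
    return ll


def saturated_moments(Y, tol=1e-10, max_iter=2000):
    """FIML estimates of the unstructured mean and covariance.

    Closed form for complete data; EM over missingness patterns
    otherwise. Returns ``(mean, cov, loglik)``.
    """
    patterns = PatternData(np.asarray(Y, dtype=float))
    Yk = patterns.Y
    n, p = Yk.shape
    if patterns.complete:
        mu = Yk.mean(axis=0)
        Sigma = np.cov(Yk.T, ddof=0).reshape(p, p)
        ll, _, _ = _gaussian_ll_grad(mu, Sigma, patterns, want_grad=False)
        return mu, Sigma, ll

    # initialize from available-case moments
    mu = np.nanmean(Yk, axis=0)
    Sigma = np.diag(np.nanvar(Yk, axis=0, ddof=0) + 1e-6)
    last = -np.inf
    for _ in range(max_iter):
        sumx = np.zeros(p)
        sumxx = np.zeros((p, p))
        for (o, Yg), rows in zip(patterns.groups, patterns.row_groups):
            m = np.setdiff1d(np.arange(p), o)
            ng = Yg.shape[0]
            X = np.empty((ng, p))
            X[:, o] = Yg
            if m.size:
                Soo = Sigma[np.ix_(o, o)]
                Smo = Sigma[np.ix_(m, o)]
                B = np.linalg.solve(Soo, Smo.T).T  # m x o
                X[:, m] = mu[m] + (Yg - mu[o]) @ B.T
                condS = Sigma[np.ix_(m, m)] - B @ Smo.T
                add = np.zeros((p, p))
                add[np.ix_(m, m)] = ng * condS
                sumxx += add
            sumx += X.sum(axis=0)
            sumxx += X.T @ X
        mu = sumx / n
        Sigma = sumxx / n - np.outer(mu, mu)
        ll, _, _ = _gaussian_ll_grad(mu, Sigma, patterns, want_grad=False)
        if ll - last < tol * max(1.0, abs(ll)):
            break
        last = ll
    return mu, Sigma, ll


def independence_loglik(Y):
    """FIML log-likelihood and free-parameter count of the independence
    baseline (free means and variances, zero covariances); closed form
    because the likelihood factorizes per variable."""
    Y = np.asarray(Y, dtype=float)
    keep = ~np.isnan(Y).all(axis=1)
    Y = Y[keep]
    ll = 0.0
    for j in range(Y.shape[1]):
        col = Y[:, j]
        col = col[~np.isnan(col)]
        v = col.var(ddof=0)
        ll += -0.5 * col.size * (_LOG2PI + math.log(v) + 1.0)
    return ll


def pairwise_moments(Y):
    """Pairwise-complete sample means and ML covariances."""
    Y = np.asarray(Y, dtype=float)
    p = Y.shape[1]
    mean = np.nanmean(Y, axis=0)
    cov = np.empty((p, p))
    for i in range(p):
        for j in range(i + 1):
            cols = Y[:, [i, j]]
            ok = ~np.isnan(cols).any(axis=1)
            xi, xj = cols[ok, 0], cols[ok, 1]
            c = ((xi - xi.mean()) * (xj - xj.mean())).mean()
            cov[i, j] = cov[j, i] = c
    return mean, cov


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

class StructuralModel:
    """Linear SEM estimated by (FI)ML.

    Parameters
    ----------
    spec : ModelSpec or dict
        Measurement and structural specification.
    table : SubjectTable or DataFrame
        Subject-level data; NaN marks missing entries.
    """

    def __init__(self, spec, table):
        if isinstance(spec, dict):
            spec = ModelSpec.from_dict(spec)
        self.spec = spec
        self.table = as_subject_table(table)
        self.compiled = compile_model(spec)
        p = self.compiled.p
        n_moments = p * (p + 1) // 2 + p
        self.df = n_moments - self.compiled.n_free
        if self.df < 0:
            raise SpecificationError(
                f"model not identified: {self.compiled.n_free} free parameters for "
                f"{n_moments} observed moments")
        self.patterns = PatternData(self.table.numeric(self.compiled.obs))
        self.n_effective = self.patterns.n

    # -- likelihood --------------------------------------------------
    def loglik_grad(self, theta_raw, want_grad=True):
        """Log-likelihood (and gradient w.r.t. raw parameters)."""
        cm = self.compiled
        A, S, a = cm.build(theta_raw)
        t, p = cm.t, cm.p
        I = np.eye(t)
        try:
            B = np.linalg.solve(I - A, I)
        except np.linalg.LinAlgError:
            return (-np.inf, None) if want_grad else -np.inf
        P = B[:p, :]
        mu = P @ a
        Sigma = P @ S @ P.T
        ll, G, gmu = _gaussian_ll_grad(mu, Sigma, self.patterns, want_grad)
        if not want_grad:
            return ll
        if not np.isfinite(ll):
            return ll, None
        PGP = P.T @ G @ P
        dA = 2.0 * PGP @ S @ B.T + np.outer(P.T @ gmu, B @ a)
        da = P.T @ gmu
        grad = np.empty(cm.n_free)
        for k, pr in enumerate(cm.params):
            if pr.kind == "A":
                grad[k] = dA[pr.i, pr.j]
            elif pr.kind == "S":
                grad[k] = PGP[pr.i, pr.i] if pr.i == pr.j else 2.0 * PGP[pr.i, pr.j]
            else:
                grad[k] = da[pr.i]
        return ll, grad

    def loglik(self, theta_raw):
        return self.loglik_grad(theta_raw, want_grad=False)

    def implied_moments(self, theta_raw):
        cm = self.compiled
        A, S, a = cm.build(theta_raw)
        B = np.linalg.solve(np.eye(cm.t) - A, np.eye(cm.t))
        mu_full = B @ a
        Sigma_full = B @ S @ B.T
        return mu_full, Sigma_full

    def factor_scores(self, theta_raw, table=None):
        """Regression-method latent scores at the given parameters.

        Subjects are scored from their observed indicator subset via the
        conditional expectation under the implied joint distribution of
        observed variables and latents; nothing observed gives NaN.
        """
        cm = self.compiled
        table = self.table if table is None else as_subject_table(table)
        Y = table.numeric(cm.obs)
        mu_full, Sigma_full = self.implied_moments(np.asarray(theta_raw, float))
        p, t = cm.p, cm.t
        lat_idx = np.arange(p, t)
        scores = np.full((Y.shape[0], t - p), np.nan)
        mask = ~np.isnan(Y)
        pats, inv = np.unique(mask, axis=0, return_inverse=True)
        for g in range(pats.shape[0]):
            o = np.flatnonzero(pats[g])
            rows = np.flatnonzero(inv == g)
            if o.size == 0:
                continue
            Soo = Sigma_full[np.ix_(o, o)]
            Slo = Sigma_full[np.ix_(lat_idx, o)]
            W = np.linalg.solve(Soo, Slo.T)  # o x m
            R = Y[np.ix_(rows, o)] - mu_full[o]
            scores[rows] = mu_full[lat_idx] + R @ W
        return pd.DataFrame(scores, columns=cm.lats)

    # -- fitting -----------------------------------------------------
    def fit(self, start=None, restarts=5, compute_se=True, gtol=1e-5, seed=0):
        """Maximize the casewise likelihood; returns :class:`SEMResults`.

        Non-convergence is flagged on the result (``converged`` False
        with the achieved gradient norm), never silent.
        """
        cm = self.compiled
        n = self.n_effective
        theta0 = np.asarray(start, float) if start is not None else start_values(cm, self.patterns.Y)
        rng = np.random.default_rng(seed)

        def objective(x):
            raw = cm.from_optim(x)
            ll, g = self.loglik_grad(raw)
            if not np.isfinite(ll) or g is None:
                return 1e10, np.zeros_like(x)
            return -ll / n, -(g * cm.jac_optim(x)) / n

        x0 = cm.to_optim(theta0)
        best = _lbfgs_with_restarts(objective, x0, gtol, restarts, rng)
        fun, gnorm, xhat = best
        converged = gnorm < gtol
        if not converged:
            warnings.warn(
                f"optimizer stopped with gradient norm {gnorm:.2e} (tolerance {gtol:.0e})",
                ConvergenceWarning, stacklevel=2)
        theta = cm.from_optim(xhat)
        ll = self.loglik(theta)

        se = np.full(cm.n_free, np.nan)
        cov_params = None
        if compute_se:
            H = self._observed_information(theta)
            try:
                cov_params = np.linalg.inv(H)
                d = np.diag(cov_params)
                se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
            except np.linalg.LinAlgError:
                warnings.warn("observed information is singular; no standard errors",
                              ConvergenceWarning, stacklevel=2)

        # saturated and baseline references for chi-square and indices
        mu_sat, cov_sat, ll_sat = saturated_moments(self.patterns.Y)
        ll_base = independence_loglik(self.patterns.Y)
        p = cm.p
        df_base = (p * (p + 1) // 2 + p) - 2 * p
        chi2 = max(2.0 * (ll_sat - ll), 0.0)
        chi2_base = max(2.0 * (ll_sat - ll_base), 0.0)
        mu_full, Sigma_full = self.implied_moments(theta)
        mean_pw, cov_pw = pairwise_moments(self.patterns.Y)
        idx = fit_indices(
            chi2, self.df, n, chi2_base, df_base,
            observed_cov=cov_pw, implied_cov=Sigma_full[:p, :p],
            observed_mean=mean_pw, implied_mean=mu_full[:p],
        )
        return SEMResults(
            model=self, params=pd.Series(theta, index=cm.names),
            se=pd.Series(se, index=cm.names), cov_params=cov_params,
            loglik=ll, chi_square=chi2, df=self.df, n_effective=n,
            indices=idx, converged=converged, gradient_norm=gnorm,
            loglik_saturated=ll_sat, loglik_baseline=ll_base, df_baseline=df_base,
        )

    def _observed_information(self, theta, h=1e-5):
        """Negative Hessian of the log-likelihood by central differences
        of the analytic gradient (raw parameter scale)."""
        m = theta.size
        H = np.zeros((m, m))
        for k in range(m):
            step = h * max(1.0, abs(theta[k]))
            tp, tm = theta.copy(), theta.copy()
            tp[k] += step
            tm[k] -= step
            _, gp = self.loglik_grad(tp)
            _, gm = self.loglik_grad(tm)
            if gp is None or gm is None:
                return np.full((m, m), np.nan)
            H[:, k] = -(gp - gm) / (2.0 * step)
        return 0.5 * (H + H.T)


class SEMResults:
    """Estimates, uncertainties, and fit diagnostics for one SEM fit."""

    def __init__(self, model, params, se, cov_params, loglik, chi_square, df,
                 n_effective, indices, converged, gradient_norm,
                 loglik_saturated, loglik_baseline, df_baseline):
        self.model = model
        self.params = params
        self.se = se
        self.cov_params = cov_params
        self.loglik = loglik
        self.chi_square = chi_square
        self.df = df
        self.n_effective = n_effective
        self.indices = indices
        self.converged = converged
        self.gradient_norm = gradient_norm
        self.loglik_saturated = loglik_saturated
        self.loglik_baseline = loglik_baseline
        self.df_baseline = df_baseline

    @property
    def zvalues(self):
        return self.params / self.se

    @property
    def pvalues(self):
        return pd.Series(2.0 * stats.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def n_free(self):
        return len(self.params)

    @property
    def aic(self):
        return -2.0 * self.loglik + 2.0 * self.n_free

    # -- standardization --------------------------------------------
    @property
    def standardized(self):
        """Standardized estimates (beta scale) from model-implied variances."""
        cm = self.model.compiled
        _, Sigma_full = self.model.implied_moments(self.params.to_numpy())
        sd = np.sqrt(np.clip(np.diag(Sigma_full), 0.0, None))
        if np.any(sd <= 0):
            raise ValueError("zero model-implied variance; cannot standardize")
        out = {}
        for val, pr in zip(self.params.to_numpy(), cm.params):
            if pr.kind == "A":
                out[pr.name] = val * sd[pr.j] / sd[pr.i]
            elif pr.kind == "S":
                out[pr.name] = val / (sd[pr.i] * sd[pr.j])
            else:
                out[pr.name] = val / sd[pr.i]
        return pd.Series(out)

    # -- factor scores ----------------------------------------------
    def factor_scores(self, table=None):
        """Regression-method (conditional expectation) latent scores at
        the fitted parameters; partial data are scored from the
        observed subset."""
        return self.model.factor_scores(self.params.to_numpy(), table)

    # -- reporting ---------------------------------------------------
    def summary(self):
        std = self.standardized
        lines = [
            "Structural equation model (FIML)",
            f"  n = {self.n_effective}, free parameters = {self.n_free}, df = {self.df}",
            f"  log-likelihood = {self.loglik:.3f}, chi2 = {self.chi_square:.3f}",
            "  indices: "
            + ", ".join(f"{k} = {v:.4f}" if np.isfinite(v) else f"{k} = n/a"
                        for k, v in self.indices.items()),
            f"  converged: {self.converged} (|grad| = {self.gradient_norm:.2e})",
            "",
            f"  {'parameter':<28}{'estimate':>10}{'std.err':>10}{'z':>8}{'p':>8}{'std':>9}",
        ]
        for name in self.params.index:
            est, s = self.params[name], self.se[name]
            z = est / s if s and np.isfinite(s) else np.nan
            pv = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
            lines.append(
                f"  {name:<28}{est:>10.4f}{s:>10.4f}{z:>8.2f}{pv:>8.3f}{std[name]:>9.4f}")
        return "\n".join(lines)

    def to_frame(self):
        return pd.DataFrame({
            "estimate": self.params, "se": self.se,
            "z": self.zvalues, "p": self.pvalues,
            "standardized": self.standardized,
        })


def fit_sem(spec, table, **kwargs) -> SEMResults:
    """Convenience wrapper: build a :class:`StructuralModel` and fit it."""
    return StructuralModel(spec, table).fit(**kwargs)
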