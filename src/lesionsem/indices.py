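"""Global fit indices and nested-model tests for covariance-structure models.

Conventions (one of several in circulation, fixed here and asserted by
the test suite):

* ``chi2_df_ratio = chi2 / df`` (not applicable at df = 0),
* ``rmsea = sqrt(max(chi2 - df, 0) / (df * n))`` with the analysis n in
  the denominator,
* ``cfi = 1 - max(chi2 - df, 0) / max(chi2_b - df_b, chi2 - df, 0)``
  against the independence baseline,
* ``srmr`` = root mean square of the standardized residuals of the
  covariance (and, when supplied, mean) structure.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

__all__ = ["fit_indices", "srmr", "chi2_difference"]


def srmr(observed_cov, implied_cov, observed_mean=None, implied_mean=None):
    """Standardized root mean square residual.

    Residual covariances are standardized by the observed variances;
    mean residuals (optional) by the observed standard deviations. The
    average runs over the p(p+1)/2 lower-triangle covariance elements
    plus, when means are given, the p mean elements.
    """
    S = np.asarray(observed_cov, dtype=float)
    M = np.asarray(implied_cov, dtype=float)
    if S.shape != M.shape or S.shape[0] != S.shape[1]:
        raise ValueError("covariance matrices must be square and congruent")
    d = np.sqrt(np.diag(S))
    denom = np.outer(d, d)
    resid = (S - M) / denom
    il, jl = np.tril_indices(S.shape[0])
    terms = list(resid[il, jl] ** 2)
    if observed_mean is not None:
        m_res = (np.asarray(observed_mean, float) - np.asarray(implied_mean, float)) / d
        terms.extend(m_res**2)
    return float(np.sqrt(np.mean(terms)))


def fit_indices(
    chi_square,
    df,
    n,
    chi_square_baseline=None,
    df_baseline=None,
    observed_cov=None,
    implied_cov=None,
    observed_mean=None,
    implied_mean=None,
):
    """Assemble the standard absolute and incremental fit indices.

    Returns a dict with ``chi2_df_ratio``, ``rmsea``, ``cfi`` (NaN
    without a baseline), and ``srmr`` (NaN without moment matrices).
    Ratio and RMSEA are NaN for a saturated model (df = 0).
    """
    if df < 0:
        raise ValueError("negative degrees of freedom")
    if n < 2:
        raise ValueError("need n >= 2")
    out = {}
    if df == 0:
        out["chi2_df_ratio"] = math.nan
        out["rmsea"] = math.nan
    else:
        out["chi2_df_ratio"] = chi_square / df
        out["rmsea"] = math.sqrt(max(chi_square - df, 0.0) / (df * n))
    if chi_square_baseline is None or df_baseline is None:
        out["cfi"] = math.nan
    else:
        num = max(chi_square - df, 0.0)
        den = max(chi_square_baseline - df_baseline, chi_square - df, 0.0)
        if not np.isfinite(den) or den <= 1e-12:
            out["cfi"] = 1.0 if num <= 1e-12 else math.nan
        else:
            out["cfi"] = 1.0 - num / den
    if observed_cov is not None and implied_cov is not None:
        out["srmr"] = srmr(observed_cov, implied_cov, observed_mean, implied_mean)
    else:
        out["srmr"] = math.nan
    return out


def chi2_difference(restricted, full, tol=1e-2):
    """Likelihood-ratio (chi-square difference) test of nested fits.

    Parameters are two fitted results carrying ``loglik`` and ``df``
    (restricted must be nested in full: higher df, lower likelihood).

    Returns a dict with ``delta_chi2``, ``delta_df``, ``p``.
    """
    delta = 2.0 * (full.loglik - restricted.loglik)
    delta_df = restricted.df - full.df
    if delta_df < 0:
        raise ValueError("restricted model must have more degrees of freedom")
    if delta < -tol:
        raise ValueError(
            f"likelihood of the full model is below the restricted one "
            f"(delta chi2 = {delta:.4f}); models non-nested or not converged")
    delta = max(delta, 0.0)
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(delta, delta_df))
    return {"delta_chi2": delta, "delta_df": delta_df, "p": p}
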