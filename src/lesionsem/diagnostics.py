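"""Influence diagnostics for the simplified (factor-score) regressions.

The latent-variable analyses are cross-checked with ordinary
least-squares regressions of factor scores on the predictors plus
covariates; Cook's distance flags influential cases (conventional
threshold 1).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SpecificationError

__all__ = ["regression_diagnostics", "RegressionDiagnostics"]


class RegressionDiagnostics:
    """OLS coefficients, per-subject Cook's distances, and flags."""

    def __init__(self, params, cooks_distance, flags, threshold, ols_results):
        self.params = params
        self.cooks_distance = cooks_distance
        self.flags = flags
        self.threshold = threshold
        self.ols_results = ols_results

    def summary(self):
        lines = [
            "OLS regression with influence diagnostics",
            f"  n = {int(self.ols_results.nobs)},"
            f" max Cook's distance = {self.cooks_distance.max():.4f}",
            f"  flagged (> {self.threshold:g}): "
            + (", ".join(map(str, self.flags)) if len(self.flags) else "none"),
        ]
        return "\n".join(lines)


def regression_diagnostics(y, X, threshold=1.0, add_constant=True):
    """OLS of ``y`` on ``X`` with Cook's distance per subject.

    Parameters
    ----------
    y : array-like or Series
        Response (e.g. factor scores).
    X : DataFrame or 2-D array
        Predictors and covariates; an intercept column is added unless
        ``add_constant`` is False.
    threshold : float
        Cook's distance above which a case is flagged (default 1).

    Raises
    ------
    SpecificationError
        If the design is rank deficient, naming the collinear columns.
    """
    Xd = pd.DataFrame(X).copy()
    yv = pd.Series(np.asarray(y, dtype=float), index=Xd.index)
    ok = ~(Xd.isna().any(axis=1) | yv.isna())
    Xd, yv = Xd[ok], yv[ok]
    if len(yv) <= Xd.shape[1] + int(add_constant):
        raise SpecificationError("need more observations than predictors")
    if add_constant:
        Xd = sm.add_constant(Xd)
    mat = Xd.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns via QR pivoting on the diagonal
        _, R = np.linalg.qr(mat)
        bad = [str(Xd.columns[j]) for j in range(mat.shape[1])
               if abs(R[j, j]) < 1e-10 * max(1.0, abs(R[0, 0]))]
        raise SpecificationError(f"rank-deficient design; collinear columns: {bad}")
    res = sm.OLS(yv.to_numpy(), mat).fit()
    cooks = pd.Series(res.get_influence().cooks_distance[0], index=yv.index)
    flags = cooks.index[cooks > threshold].tolist()
    params = pd.Series(res.params, index=Xd.columns)
    return RegressionDiagnostics(params, cooks, flags, threshold, res)
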