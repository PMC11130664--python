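"""Weighted least-squares core shared by the observational and MR modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["LinearFit", "wls", "RankDeficientError"]


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


@dataclass
class LinearFit:
    """A fitted (weighted) linear model.

    ``params``/``bse``/``pvalues`` are indexed by ``names``. Residuals and
    fitted values are on the original (unweighted) scale; ``weights`` holds
    the sample weights used in estimation.
    """

    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    resid: np.ndarray
    fitted: np.ndarray
    names: list
    weights: np.ndarray
    nobs: int
    df_resid: int
    scale: float
    rss: float = field(default=np.nan)

    @property
    def tvalues(self) -> np.ndarray:
        return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid)

    def coef(self, name: str) -> tuple[float, float, float]:
        """(beta, se, p) for a named column."""
        j = self.names.index(name)
        return float(self.params[j]), float(self.bse[j]), float(self.pvalues[j])


def _collinear_columns(Xw: np.ndarray, names) -> list:
    """Columns that are (numerically) in the span of the preceding ones."""
    bad = []
    kept = np.empty((Xw.shape[0], 0))
    for j in range(Xw.shape[1]):
        col = Xw[:, j : j + 1]
        if kept.shape[1] == 0:
            resid = col
        else:
            coef, *_ = np.linalg.lstsq(kept, col, rcond=None)
            resid = col - kept @ coef
        norm = np.linalg.norm(col)
        if norm == 0 or np.linalg.norm(resid) < 1e-8 * max(norm, 1.0):
            bad.append(names[j])
        else:
            kept = np.hstack([kept, col])
    return bad


def wls(y: np.ndarray, X: np.ndarray, weights=None, names=None) -> LinearFit:
    """Weighted least squares via the scaled normal equations.

    weights are relative sample weights (all-ones reproduces OLS exactly);
    the error scale is RSS_w / (n - k).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if names is None:
        names = [f"x{j}" for j in range(k)]
    names = list(names)
    if len(y) != n:
        raise ValueError("y and X have incompatible shapes")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError("weights must be one per observation")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    sw = np.sqrt(w)
    Xw = X * sw[:, None]
    yw = y * sw
    rank = np.linalg.matrix_rank(Xw)
    if rank < k:
        raise RankDeficientError(_collinear_columns(Xw, names))
    params, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    fitted = X @ params
    resid = y - fitted
    rss = float(np.sum(w * resid**2))
    df_resid = n - k
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    scale = rss / df_resid
    XtWX_inv = np.linalg.inv(Xw.T @ Xw)
    cov = scale * XtWX_inv
    bse = np.sqrt(np.diag(cov))
    return LinearFit(
        params=params,
        bse=bse,
        cov_params=cov,
        resid=resid,
        fitted=fitted,
        names=names,
        weights=w,
        nobs=n,
        df_resid=df_resid,
        scale=scale,
        rss=rss,
    )
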