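"""Meal-response phenotypes via errors-in-variables (Deming) regression.

For each metabolite the postprandial abundance is regressed on the fasting
abundance with a Deming fit, which allows measurement error in both
variables. The vertical residuals (postprandial units) are the response
trait: positive values mean a larger postprandial abundance than the
fasted level predicts. A simple delta (postprandial minus fasting) is
provided as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DemingFit",
    "DegenerateFitError",
    "deming_fit",
    "deming_residuals",
    "delta_response",
    "build_response_matrix",
]

log = logging.getLogger(__name__)


class DegenerateFitError(ValueError):
    """Raised when the fit carries no orientation information."""


@dataclass(frozen=True)
class DemingFit:
    """Closed-form errors-in-variables fit of y on x.

    ``lam`` is the ratio of the outcome-error variance to the
    predictor-error variance (1 = equal error in both states).
    """

    intercept: float
    slope: float
    lam: float
    n_used: int

    def predict(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def deming_fit(x, y, lam: float = 1.0) -> DemingFit:
    """Fit y = a + b*x minimizing sum (y - a - b x)^2 / (lam + b^2).

    Closed form: with sxx, syy, sxy the centered sums of squares/products,
        b = [syy - lam*sxx + sqrt((syy - lam*sxx)^2 + 4*lam*sxy^2)] / (2*sxy)
        a = ybar - b*xbar
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    xs, ys = _complete_pairs(x, y)
    n = xs.size
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")
    xbar, ybar = xs.mean(), ys.mean()
    dx, dy = xs - xbar, ys - ybar
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    sxy = float(dx @ dy)
    if sxx == 0.0:
        raise DegenerateFitError("var(x) is zero")
    if sxy == 0.0:
        raise DegenerateFitError("cov(x, y) is zero: no orientation information")
    d = syy - lam * sxx
    slope = (d + np.sqrt(d * d + 4.0 * lam * sxy * sxy)) / (2.0 * sxy)
    intercept = ybar - slope * xbar
    return DemingFit(intercept=float(intercept), slope=float(slope), lam=float(lam), n_used=int(n))


def deming_residuals(fit: DemingFit, x, y) -> np.ndarray:
    """Vertical residuals y - (a + b*x); missing values propagate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return y - fit.predict(x)


def delta_response(x, y) -> np.ndarray:
    """Simple change score: y - x elementwise; missing values propagate."""
    return np.asarray(y, dtype=float) - np.asarray(x, dtype=float)


def build_response_matrix(
    fasting: pd.DataFrame,
    postprandial: pd.DataFrame,
    method: str = "deming",
    lam: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trait response matrix plus a table of the fits used.

    Parameters
    ----------
    fasting, postprandial
        QC'd individuals x traits matrices sharing index and columns.
    method
        "deming" (residuals of the Deming fit) or "delta" (ignores ``lam``).

    Returns
    -------
    (response, fits)
        ``response`` mirrors the input layout (NaN wherever either state is
        missing); ``fits`` has one row per successfully fitted trait with
        columns trait/intercept/slope/lam/n_used. Degenerate traits are
        skipped and logged.
    """
    if method not in ("deming", "delta"):
        raise ValueError(f"unknown method {method!r}")
    if not fasting.columns.equals(postprandial.columns) or not fasting.index.equals(
        postprandial.index
    ):
        raise ValueError("fasting and postprandial matrices must share index and columns")
    resp = pd.DataFrame(np.nan, index=fasting.index, columns=fasting.columns)
    rows = []
    for trait in fasting.columns:
        x = fasting[trait].to_numpy(dtype=float)
        y = postprandial[trait].to_numpy(dtype=float)
        if method == "delta":
            resp[trait] = delta_response(x, y)
            continue
        try:
            fit = deming_fit(x, y, lam=lam)
        except (DegenerateFitError, ValueError) as exc:
            log.warning("trait %s skipped: %s", trait, exc)
            continue
        resp[trait] = deming_residuals(fit, x, y)
        rows.append(
            {
                "trait": trait,
                "intercept": fit.intercept,
                "slope": fit.slope,
                "lam": fit.lam,
                "n_used": fit.n_used,
            }
        )
    if method == "deming":
        fitted = [r["trait"] for r in rows]
        resp = resp[fitted] if fitted else resp.iloc[:, :0]
    fits = pd.DataFrame(rows, columns=["trait", "intercept", "slope", "lam", "n_used"])
    return resp, fits
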