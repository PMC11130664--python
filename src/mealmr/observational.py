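"""Weighted multivariable association of metabolite traits with BMI.

The mean model is metabolite ~ visit_date + subpopulation + age + sex +
BMI, fitted by weighted least squares (a Gaussian identity-link GLM).
Each fit also reports a Breusch-Pagan homoskedasticity test and
sequential (type I) eta-squared variance decompositions with BMI entered
last.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import LinearFit, wls

__all__ = [
    "DEFAULT_COVARIATES",
    "build_design",
    "fit_weighted_glm",
    "breusch_pagan",
    "anova_eta_squared",
    "describe_states",
    "covariable_screen",
    "association_scan",
]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = ["visit_date", "subpopulation", "age", "sex"]


def _encode(cohort: pd.DataFrame, col: str) -> tuple[np.ndarray, str]:
    v = cohort[col]
    if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype) or v.dtype == bool:
        levels = sorted(pd.unique(v.dropna()))
        if len(levels) < 2:
            raise ValueError(f"covariable {col} does not vary")
        if len(levels) > 2:
            raise ValueError(f"covariable {col} has >2 levels; pre-encode it")
        return (v == levels[1]).to_numpy(dtype=float), f"{col}[{levels[1]}]"
    return v.to_numpy(dtype=float), col


def build_design(
    cohort: pd.DataFrame, covariates=DEFAULT_COVARIATES, exposure: str = "bmi"
) -> tuple[np.ndarray, list]:
    """Design matrix [intercept, covariates..., exposure] with binary
    covariables dummy-coded. The exposure column comes last so the
    sequential decomposition attributes its variance after the covariates."""
    cols, names = [np.ones(len(cohort))], ["intercept"]
    for c in list(covariates) + [exposure]:
        arr, name = _encode(cohort, c)
        cols.append(arr)
        names.append(name)
    return np.column_stack(cols), names


def fit_weighted_glm(
    outcome: pd.Series,
    cohort: pd.DataFrame,
    use_weights: bool = True,
    covariates=DEFAULT_COVARIATES,
    exposure: str = "bmi",
) -> tuple[dict, LinearFit]:
    """Per-trait weighted association fit; complete cases only.

    Returns a result record (trait/beta/se/p/n/eta2/bp_p for the exposure
    coefficient) plus the underlying :class:`LinearFit`.
    """
    df = cohort.loc[cohort.index.intersection(outcome.index)].copy()
    y = outcome.reindex(df.index).to_numpy(dtype=float)
    ok = np.isfinite(y)
    for c in list(covariates) + [exposure]:
        v = df[c]
        ok &= v.notna().to_numpy()
        if np.issubdtype(np.asarray(v).dtype, np.number):
            ok &= np.isfinite(v.to_numpy(dtype=float))
    df = df.loc[ok]
    y = y[ok]
    if len(df) < 10:
        raise ValueError(f"only {len(df)} complete cases")
    X, names = build_design(df, covariates, exposure)
    w = df["sample_weight"].to_numpy(dtype=float) if use_weights else None
    fit = wls(y, X, weights=w, names=names)
    beta, se, p = fit.coef(exposure)
    bp_stat, bp_p = breusch_pagan(fit, X)
    eta2_model, eta2_exposure = anova_eta_squared(y, X, names, fit.weights, exposure)
    record = {
        "beta": beta,
        "se": se,
        "p": p,
        "n": int(fit.nobs),
        "eta2_model": eta2_model,
        "eta2_bmi": eta2_exposure,
        "bp_p": bp_p,
    }
    return record, fit


def breusch_pagan(fit: LinearFit, X: np.ndarray) -> tuple[float, float]:
    """Lagrange-multiplier homoskedasticity test.

    Regresses the squared (weighted) residuals on the mean-model design;
    LM = n * R^2, chi-square with k - 1 df (intercept excluded).
    """
    e2 = fit.weights * fit.resid**2
    n, k = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, e2, rcond=None)
    pred = X @ coef
    tss = np.sum((e2 - e2.mean()) ** 2)
    rss = np.sum((e2 - pred) ** 2)
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    lm = n * r2
    df = k - 1
    p = float(stats.chi2.sf(lm, df)) if df > 0 else 1.0
    return float(lm), p


def anova_eta_squared(
    y: np.ndarray, X: np.ndarray, names: list, weights: np.ndarray, exposure: str = "bmi"
) -> tuple[float, float]:
    """Sequential (type I) eta-squared with the exposure entered last.

    eta2_exposure = sequential SS(exposure) / total SS; eta2_model is the
    summed sequential SS of all non-intercept terms over total SS.
    Weighted sums of squares are used when weights vary.
    """
    w = weights
    ybar = np.average(y, weights=w)
    tss = float(np.sum(w * (y - ybar) ** 2))
    if tss == 0:
        raise ValueError("zero total sum of squares")
    sw = np.sqrt(w)
    rss_prev = tss
    seq_ss = {}
    for j in range(2, X.shape[1] + 1):
        Xj = X[:, :j] * sw[:, None]
        coef, _, _, _ = np.linalg.lstsq(Xj, y * sw, rcond=None)
        rss = float(np.sum((y * sw - Xj @ coef) ** 2))
        seq_ss[names[j - 1]] = rss_prev - rss
        rss_prev = rss
    exposure_name = next(n for n in seq_ss if n == exposure or n.startswith(f"{exposure}["))
    eta2_model = sum(seq_ss.values()) / tss
    eta2_exposure = seq_ss[exposure_name] / tss
    return float(eta2_model), float(eta2_exposure)


def describe_states(
    fasting: pd.DataFrame, postprandial: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-trait fasting vs postprandial descriptives.

    Paired t statistic and P, mean change, and the 2.5/97.5 percentile
    interval of the per-individual change distribution; the significance
    flag is Bonferroni-corrected by the number of traits tested.
    """
    n_traits = fasting.shape[1]
    thr = alpha / n_traits
    rows = []
    for trait in fasting.columns:
        x = fasting[trait].to_numpy(dtype=float)
        y = postprandial[trait].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        d = y[ok] - x[ok]
        rec = {
            "trait": trait,
            "n": int(ok.sum()),
            "mean_delta": float(d.mean()) if d.size else np.nan,
            "delta_lo": float(np.percentile(d, 2.5)) if d.size else np.nan,
            "delta_hi": float(np.percentile(d, 97.5)) if d.size else np.nan,
        }
        if d.size < 3 or np.allclose(d.std(ddof=1), 0.0):
            if d.size >= 3 and np.allclose(d, 0.0):
                # no change at all: no evidence of a difference
                rec.update({"t": 0.0, "p": 1.0, "zero_variance": True, "significant": False})
            else:
                rec.update({"t": np.nan, "p": np.nan, "zero_variance": True, "significant": False})
        else:
            t, p = stats.ttest_rel(y[ok], x[ok])
            rec.update(
                {"t": float(t), "p": float(p), "zero_variance": False, "significant": bool(p < thr)}
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = thr
    return out


def _univariable_p(y: np.ndarray, x: np.ndarray, w=None) -> float:
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 10 or np.std(x[ok]) == 0:
        return np.nan
    X = np.column_stack([np.ones(ok.sum()), x[ok]])
    fit = wls(y[ok], X, weights=None if w is None else w[ok], names=["intercept", "x"])
    return fit.coef("x")[2]


def covariable_screen(
    cohort: pd.DataFrame,
    metabolites: pd.DataFrame,
    covariables: list,
    m_eff: int,
    alpha: float = 0.05,
    use_weights: bool = True,
) -> pd.DataFrame:
    """Univariable confounder screen.

    Every covariable is tested against BMI and against the PGS; those
    associated with the PGS (P below alpha/m_eff) are additionally tested
    against each metabolite trait. Non-varying covariables are skipped.
    """
    thr = alpha / m_eff
    w = cohort["sample_weight"].to_numpy(dtype=float) if use_weights else None
    bmi = cohort["bmi"].to_numpy(dtype=float)
    pgs = cohort["pgs"].to_numpy(dtype=float) if "pgs" in cohort else None
    rows = []
    for cov in covariables:
        try:
            x, _ = _encode(cohort, cov)
        except ValueError as exc:
            log.info("covariable %s skipped: %s", cov, exc)
            continue
        finite = x[np.isfinite(x)]
        if finite.size == 0 or np.std(finite) == 0:
            log.info("covariable %s skipped: does not vary", cov)
            continue
        p_bmi = _univariable_p(bmi, x, w)
        p_pgs = _univariable_p(pgs, x, w) if pgs is not None else np.nan
        pgs_assoc = bool(np.isfinite(p_pgs) and p_pgs < thr)
        rec = {
            "covariable": cov,
            "p_bmi": p_bmi,
            "flag_bmi": bool(np.isfinite(p_bmi) and p_bmi < thr),
            "p_pgs": p_pgs,
            "flag_pgs": pgs_assoc,
            "n_metabolites_assoc": 0,
        }
        if pgs_assoc:
            n_hits = 0
            mets = metabolites.reindex(cohort.index)
            for trait in metabolites.columns:
                p_met = _univariable_p(mets[trait].to_numpy(dtype=float), x, w)
                if np.isfinite(p_met) and p_met < thr:
                    n_hits += 1
            rec["n_metabolites_assoc"] = n_hits
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = thr
    return out


def association_scan(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    state: str,
    use_weights: bool = True,
    covariates=DEFAULT_COVARIATES,
    analysis_tag: str = "weighted",
) -> pd.DataFrame:
    """Observational estimate table: one row per trait."""
    rows = []
    cohort_idx = cohort.set_index("individual_id") if "individual_id" in cohort else cohort
    for trait in matrix.columns:
        try:
            rec, _ = fit_weighted_glm(
                matrix[trait], cohort_idx, use_weights=use_weights, covariates=covariates
            )
        except ValueError as exc:
            log.warning("trait %s (%s) skipped: %s", trait, state, exc)
            continue
        rec.update({"trait": trait, "state": state, "analysis_tag": analysis_tag})
        rows.append(rec)
    cols = [
        "trait",
        "state",
        "beta",
        "se",
        "p",
        "n",
        "eta2_model",
        "eta2_bmi",
        "bp_p",
        "analysis_tag",
    ]
    return pd.DataFrame(rows, columns=cols)
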