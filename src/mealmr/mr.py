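"""One-sample Mendelian randomization by weighted two-stage least squares.

BMI is the exposure, the polygenic score the instrument, and each
metabolite trait iteratively the outcome, with the same covariates as the
observational model. Stage 1 regresses the exposure on instrument plus
covariates; stage 2 regresses the outcome on the fitted exposure plus
covariates; coefficient variance uses residuals formed with the observed
exposure (the standard 2SLS variance, not the naive stage-2 OLS one).
Sample weights, when used, apply identically in both stages.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._regression import wls
from .observational import DEFAULT_COVARIATES, breusch_pagan, build_design

__all__ = ["fit_2sls", "weak_instrument_f", "durbin_wu_hausman", "mr_scan"]

log = logging.getLogger(__name__)

WEAK_INSTRUMENT_F = 10.0
_F_CAP = 1e12


def _complete_case(outcome, cohort, covariates, exposure, instrument):
    df = cohort.loc[cohort.index.intersection(outcome.index)].copy()
    y = outcome.reindex(df.index).to_numpy(dtype=float)
    ok = np.isfinite(y)
    for c in list(covariates) + [exposure, instrument]:
        v = df[c]
        ok &= v.notna().to_numpy()
        if np.issubdtype(np.asarray(v).dtype, np.number):
            ok &= np.isfinite(v.to_numpy(dtype=float))
    return df.loc[ok], y[ok]


def _stage_matrices(df, covariates, exposure, instrument):
    C, names = build_design(df, covariates, exposure)
    x = C[:, -1]  # observed exposure
    C = C[:, :-1]  # intercept + covariates
    cnames = names[:-1]
    z = df[instrument].to_numpy(dtype=float)
    return x, z, C, cnames


def weak_instrument_f(x, z, C, weights=None) -> tuple[float, float]:
    """Partial F for the instrument in the stage-1 regression.

    F = (delta SS / 1) / (SS_full / (n - k)), P from F(1, n - k). A
    numerically exhausted residual SS yields a capped F (logged).
    """
    n = len(x)
    fit_full = wls(x, np.column_stack([C, z]), weights=weights)
    fit_red = wls(x, C, weights=weights)
    df_resid = fit_full.df_resid
    if fit_full.rss <= 1e-12 * max(fit_red.rss, 1.0):
        log.warning("stage-1 residual SS ~ 0; weak-instrument F capped at %g", _F_CAP)
        return _F_CAP, 0.0
    f = (fit_red.rss - fit_full.rss) / (fit_full.rss / df_resid)
    p = float(stats.f.sf(f, 1, df_resid))
    return float(f), p


def durbin_wu_hausman(y, x, z, C, weights=None) -> tuple[float, float]:
    """Endogeneity test via the augmented (control-function) regression.

    The stage-1 residual is added to the outcome model; the statistic is
    the squared t of its coefficient, with a chi-square(1) P value.
    """
    s1 = wls(x, np.column_stack([C, z]), weights=weights)
    r1 = x - (np.column_stack([C, z]) @ s1.params)
    if np.std(r1) < 1e-12 * max(np.std(x), 1.0):
        # exposure fully determined by instrument + covariates: no
        # endogeneity information in the control function
        log.warning("stage-1 residuals degenerate; endogeneity test returns 0")
        return 0.0, 1.0
    X_aug = np.column_stack([C, x, r1])
    names = [f"c{j}" for j in range(C.shape[1])] + ["exposure", "stage1_resid"]
    fit = wls(y, X_aug, weights=weights, names=names)
    t = fit.params[-1] / fit.bse[-1]
    stat = float(t * t)
    return stat, float(stats.chi2.sf(stat, 1))


def fit_2sls(
    outcome: pd.Series,
    cohort: pd.DataFrame,
    exposure: str = "bmi",
    instrument: str = "pgs",
    covariates=DEFAULT_COVARIATES,
    use_weights: bool = True,
) -> dict:
    """Two-stage least squares instrumental-variable fit for one trait.

    Returns a record with beta_iv/se_iv/p_iv/n plus the weak-instrument F,
    Durbin-Wu-Hausman, and Breusch-Pagan diagnostics. A weak instrument
    (F below 10) sets ``weak_instrument`` rather than suppressing the
    result.
    """
    df, y = _complete_case(outcome, cohort, covariates, exposure, instrument)
    if len(df) < 10:
        raise ValueError(f"only {len(df)} complete cases")
    x, z, C, cnames = _stage_matrices(df, covariates, exposure, instrument)
    if np.std(z) == 0:
        raise ValueError("instrument has zero variance")
    w = df["sample_weight"].to_numpy(dtype=float) if use_weights else np.ones(len(df))
    sw = np.sqrt(w)

    Z1 = np.column_stack([C, z])
    s1 = wls(x, Z1, weights=w)
    xhat = Z1 @ s1.params

    X2 = np.column_stack([C, xhat])
    names2 = cnames + [exposure]
    s2 = wls(y, X2, weights=w, names=names2)
    params = s2.params
    # 2SLS variance: residuals with the OBSERVED exposure
    X_obs = np.column_stack([C, x])
    resid = y - X_obs @ params
    n, k = X2.shape
    sigma2 = float(np.sum(w * resid**2)) / (n - k)
    Xw = X2 * sw[:, None]
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    beta_iv = float(params[-1])
    se_iv = float(se[-1])
    y_scale = max(float(np.abs(y).max()), 1.0)
    if np.sqrt(sigma2) < 1e-12 * y_scale:  # exact fit (e.g. constant outcome)
        p_iv = 1.0 if abs(beta_iv) < 1e-10 else 0.0
    else:
        t = beta_iv / se_iv
        p_iv = float(2.0 * stats.t.sf(abs(t), n - k))

    f_stat, f_p = weak_instrument_f(x, z, C, weights=w)
    dwh_stat, dwh_p = durbin_wu_hausman(y, x, z, C, weights=w)
    fit_for_bp = wls(y, X_obs, weights=w, names=names2)
    _, bp_p = breusch_pagan(fit_for_bp, X_obs)
    weak = f_stat < WEAK_INSTRUMENT_F
    if weak:
        log.warning("weak instrument (F = %.2f < %.0f)", f_stat, WEAK_INSTRUMENT_F)
    return {
        "beta_iv": beta_iv,
        "se_iv": se_iv,
        "p_iv": p_iv,
        "n": int(n),
        "f_stat": float(min(f_stat, _F_CAP)),
        "f_p": f_p,
        "dwh_stat": dwh_stat,
        "dwh_p": dwh_p,
        "bp_p": bp_p,
        "weak_instrument": bool(weak),
    }


def mr_scan(
    matrix: pd.DataFrame,
    cohort: pd.DataFrame,
    state: str,
    use_weights: bool = True,
    covariates=DEFAULT_COVARIATES,
    analysis_tag: str = "weighted",
) -> pd.DataFrame:
    """MR estimate table: one row per trait."""
    rows = []
    cohort_idx = cohort.set_index("individual_id") if "individual_id" in cohort else cohort
    for trait in matrix.columns:
        try:
            rec = fit_2sls(
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
        "beta_iv",
        "se_iv",
        "p_iv",
        "n",
        "f_stat",
        "f_p",
        "dwh_stat",
        "dwh_p",
        "bp_p",
        "weak_instrument",
        "analysis_tag",
    ]
    return pd.DataFrame(rows, columns=cols)
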