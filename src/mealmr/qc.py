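"""Metabolite matrix cleaning.

Rule order is fixed: zeros -> univariate IQR -> bivariate
fasting/postprandial screen -> sample/feature missingness filters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .response import DegenerateFitError, deming_fit, deming_residuals

__all__ = [
    "QCReport",
    "zeros_to_missing",
    "iqr_filter",
    "bivariate_outlier_filter",
    "sample_feature_filter",
    "run_qc",
]

log = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Bookkeeping for every cell/sample/trait a QC rule touched."""

    cells_set_missing: dict = field(default_factory=dict)  # rule -> {trait: count}
    samples_removed: list = field(default_factory=list)
    traits_removed: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    messages: list = field(default_factory=list)

    def record_cells(self, rule: str, trait, count: int) -> None:
        if count < 0:
            raise ValueError("counts must be nonnegative")
        self.cells_set_missing.setdefault(rule, {})
        self.cells_set_missing[rule][trait] = (
            self.cells_set_missing[rule].get(trait, 0) + int(count)
        )

    def total_cells(self, rule: str) -> int:
        return sum(self.cells_set_missing.get(rule, {}).values())

    def log(self, msg: str) -> None:
        self.messages.append(msg)
        log.info(msg)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"rule": rule, "trait": trait, "cells_set_missing": count}
            for rule, traits in self.cells_set_missing.items()
            for trait, count in traits.items()
        ]
        return pd.DataFrame(rows, columns=["rule", "trait", "cells_set_missing"])


def zeros_to_missing(matrix: pd.DataFrame, report: QCReport | None = None) -> pd.DataFrame:
    """Convert exact-zero abundances to missing; other values untouched."""
    report = report if report is not None else QCReport()
    out = matrix.copy()
    for trait in out.columns:
        zero = out[trait] == 0.0
        n = int(zero.sum())
        if n:
            out.loc[zero, trait] = np.nan
            report.record_cells("zeros", trait, n)
            if out[trait].isna().all():
                report.log(f"trait {trait}: entirely missing after zero conversion")
    return out


def iqr_filter(matrix: pd.DataFrame, k: float = 10.0, report: QCReport | None = None) -> pd.DataFrame:
    """Set missing every value more than k interquartile ranges from the
    per-trait median (computed on nonmissing values). Zero-IQR traits are
    left untouched and logged."""
    if k <= 0:
        raise ValueError("k must be > 0")
    report = report if report is not None else QCReport()
    report.params.setdefault("iqr_k", k)
    out = matrix.copy()
    for trait in out.columns:
        vals = out[trait]
        obs = vals.dropna()
        if obs.empty:
            continue
        med = obs.median()
        iqr = obs.quantile(0.75) - obs.quantile(0.25)
        if iqr == 0:
            report.log(f"trait {trait}: IQR is 0, univariate filter skipped")
            continue
        bad = (vals - med).abs() > k * iqr
        n = int(bad.sum())
        if n:
            out.loc[bad, trait] = np.nan
            report.record_cells("iqr", trait, n)
    return out


def bivariate_outlier_filter(
    fasting: pd.DataFrame,
    postprandial: pd.DataFrame,
    k: float = 10.0,
    report: QCReport | None = None,
):
    """Screen pairs against the fasting/postprandial relationship.

    Per trait a preliminary Deming fit (lambda = 1) is computed on complete
    pairs; pairs whose vertical residual lies more than ``k`` residual-IQRs
    from the residual median are set missing in both dietary states.
    Traits with fewer than 10 complete pairs are skipped with a warning.
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    if not fasting.columns.equals(postprandial.columns) or not fasting.index.equals(
        postprandial.index
    ):
        raise ValueError("matrices must share individuals and traits")
    report = report if report is not None else QCReport()
    report.params.setdefault("bivar_k", k)
    fast = fasting.copy()
    post = postprandial.copy()
    for trait in fast.columns:
        x = fast[trait].to_numpy(dtype=float)
        y = post[trait].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 10:
            report.log(f"trait {trait}: only {int(ok.sum())} complete pairs, bivariate filter skipped")
            continue
        try:
            fit = deming_fit(x[ok], y[ok], lam=1.0)
        except (DegenerateFitError, ValueError) as exc:
            report.log(f"trait {trait}: degenerate bivariate fit skipped ({exc})")
            continue
        resid = deming_residuals(fit, x, y)
        r_obs = resid[ok]
        med = np.median(r_obs)
        iqr = np.percentile(r_obs, 75) - np.percentile(r_obs, 25)
        if iqr == 0:
            report.log(f"trait {trait}: residual IQR is 0, bivariate filter skipped")
            continue
        bad = ok & (np.abs(resid - med) > k * iqr)
        n = int(bad.sum())
        if n:
            fast.loc[bad, trait] = np.nan
            post.loc[bad, trait] = np.nan
            report.record_cells("bivariate_fasting", trait, n)
            report.record_cells("bivariate_postprandial", trait, n)
    return fast, post, report


def sample_feature_filter(
    matrix: pd.DataFrame,
    sample_missing_max: float = 0.2,
    feature_missing_max: float = 0.2,
    report: QCReport | None = None,
):
    """Drop features then samples whose missingness exceeds the thresholds."""
    for name, frac in (
        ("sample_missing_max", sample_missing_max),
        ("feature_missing_max", feature_missing_max),
    ):
        if not (0.0 < frac <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1]")
    report = report if report is not None else QCReport()
    report.params.update(
        {"sample_missing_max": sample_missing_max, "feature_missing_max": feature_missing_max}
    )
    out = matrix.copy()
    feat_miss = out.isna().mean(axis=0)
    drop_feats = feat_miss[feat_miss > feature_missing_max].index.tolist()
    if drop_feats:
        out = out.drop(columns=drop_feats)
        report.traits_removed.extend(drop_feats)
        report.log(f"removed {len(drop_feats)} feature(s) above missingness {feature_missing_max}")
    if out.shape[1] == 0:
        raise ValueError("all features removed by the missingness filter")
    samp_miss = out.isna().mean(axis=1)
    drop_samps = samp_miss[samp_miss > sample_missing_max].index.tolist()
    if drop_samps:
        out = out.drop(index=drop_samps)
        report.samples_removed.extend(drop_samps)
        report.log(f"removed {len(drop_samps)} sample(s) above missingness {sample_missing_max}")
    report.log("filter order: features first, then samples")
    return out, report


def run_qc(
    fasting: pd.DataFrame,
    postprandial: pd.DataFrame,
    iqr_k: float = 10.0,
    bivar_k: float = 10.0,
    sample_missing_max: float = 0.2,
    feature_missing_max: float = 0.2,
):
    """Full cleaning chain on the paired state matrices.

    Sample/feature filters are evaluated on the column-wise concatenation
    of both states so the two matrices stay aligned; removals apply to
    both. Returns ``(fasting, postprandial, report)``.
    """
    report = QCReport()
    fast = zeros_to_missing(fasting, report)
    post = zeros_to_missing(postprandial, report)
    fast = iqr_filter(fast, k=iqr_k, report=report)
    post = iqr_filter(post, k=iqr_k, report=report)
    fast, post, report = bivariate_outlier_filter(fast, post, k=bivar_k, report=report)
    combined = pd.concat(
        {"fasting": fast, "postprandial": post}, axis=1
    )
    combined, report = sample_feature_filter(
        combined,
        sample_missing_max=sample_missing_max,
        feature_missing_max=feature_missing_max,
        report=report,
    )
    kept_samples = combined.index
    kept_traits = [
        t
        for t in fast.columns
        if ("fasting", t) in combined.columns and ("postprandial", t) in combined.columns
    ]
    fast = combined["fasting"].reindex(columns=kept_traits).loc[kept_samples]
    post = combined["postprandial"].reindex(columns=kept_traits).loc[kept_samples]
    return fast, post, report
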