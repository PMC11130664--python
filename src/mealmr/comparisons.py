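"""Comparisons of estimate vectors across states, sexes, and frameworks."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "z_diff",
    "compare_tables",
    "estimate_vector_comparison",
    "classify_associations",
    "lipoprotein_profile",
]

log = logging.getLogger(__name__)


def z_diff(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """z test for a difference between two estimates.

    z = (b1 - b2) / sqrt(se1^2 + se2^2), two-sided normal P. The two
    estimates are treated as independent, an approximation when both come
    from the same sample.
    """
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (b1 - b2) / np.sqrt(se1**2 + se2**2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def compare_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    context: str,
    corrected_threshold: float,
    beta_col: str = "beta",
    se_col: str = "se",
) -> pd.DataFrame:
    """Per-trait z tests between two aligned estimate tables."""
    a = table_a.set_index("trait")
    b = table_b.set_index("trait")
    shared = a.index.intersection(b.index)
    rows = []
    for trait in shared:
        z, p = z_diff(
            a.loc[trait, beta_col], a.loc[trait, se_col], b.loc[trait, beta_col], b.loc[trait, se_col]
        )
        rows.append(
            {
                "trait": trait,
                "context": context,
                "z": z,
                "p": p,
                "flag_nominal": bool(p < 0.05),
                "flag_corrected": bool(p < corrected_threshold),
            }
        )
    return pd.DataFrame(rows, columns=["trait", "context", "z", "p", "flag_nominal", "flag_corrected"])


def estimate_vector_comparison(
    vec_a: pd.DataFrame, vec_b: pd.DataFrame, beta_a: str = "beta", beta_b: str = "beta"
) -> dict:
    """Pearson r of the two beta vectors plus the OLS line of B on A."""
    a = vec_a.set_index("trait")[beta_a]
    b = vec_b.set_index("trait")[beta_b]
    shared = a.index.intersection(b.index)
    av = a.loc[shared].to_numpy(dtype=float)
    bv = b.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(av) & np.isfinite(bv)
    av, bv = av[ok], bv[ok]
    if av.size < 3:
        raise ValueError(f"only {av.size} shared traits with finite estimates")
    r, p = stats.pearsonr(av, bv)
    slope, intercept = np.polyfit(av, bv, 1)
    return {
        "r": float(r),
        "p": float(p),
        "intercept": float(intercept),
        "slope": float(slope),
        "n": int(av.size),
    }


def classify_associations(
    table_a: pd.DataFrame, table_b: pd.DataFrame, threshold: float, p_col: str = "p"
) -> dict:
    """Shared / A-only / B-only / neither counts over the common trait set."""
    a = table_a.set_index("trait")[p_col]
    b = table_b.set_index("trait")[p_col]
    shared_traits = a.index.intersection(b.index)
    fa = a.loc[shared_traits] < threshold
    fb = b.loc[shared_traits] < threshold
    counts = {
        "shared": int((fa & fb).sum()),
        "A_only": int((fa & ~fb).sum()),
        "B_only": int((~fa & fb).sum()),
        "neither": int((~fa & ~fb).sum()),
        "n_traits": int(len(shared_traits)),
    }
    assert counts["shared"] + counts["A_only"] + counts["B_only"] + counts["neither"] == counts[
        "n_traits"
    ]
    return counts


def lipoprotein_profile(
    estimates: pd.DataFrame, annotations: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Long-format class x size x component summary of lipoprotein betas.

    ``annotations`` maps trait -> lipoprotein_class / size_rank /
    component. Unannotated traits are kept under class "other" and
    logged. Rows are ordered by size rank within class, mirroring a
    profile plot layout.
    """
    if estimates.empty:
        log.warning("empty estimate table: returning empty profile")
        return pd.DataFrame(
            columns=["trait", "lipoprotein_class", "size_rank", "component", "beta", "se", "p", "significant"]
        )
    ann = annotations.set_index("trait")
    rows = []
    for rec in estimates.itertuples(index=False):
        if rec.trait in ann.index:
            a = ann.loc[rec.trait]
            cls, size_rank, comp = a["lipoprotein_class"], a["size_rank"], a["component"]
        else:
            log.info("trait %s unannotated; placed in class 'other'", rec.trait)
            cls, size_rank, comp = "other", np.nan, "unknown"
        rows.append(
            {
                "trait": rec.trait,
                "lipoprotein_class": cls,
                "size_rank": size_rank,
                "component": comp,
                "beta": rec.beta,
                "se": rec.se,
                "p": rec.p,
                "significant": bool(rec.p < threshold),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["lipoprotein_class", "size_rank", "component"], kind="mergesort"
    ).reset_index(drop=True)
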