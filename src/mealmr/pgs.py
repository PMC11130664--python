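"""Polygenic-score construction: harmonize GWAS weights against cohort
genotypes, align effects to the score-increasing allele, and score.

Harmonization keeps a variant if its alleles match the cohort's as-is,
keeps it with a sign flip (dosage d -> 2 - d) if they match after
swapping effect/other, and drops it for any other allele configuration
or when the folded minor allele frequencies differ by more than the
tolerance (default +/- 0.1). Palindromic variants are retained and rely
on the frequency check; no strand flipping is attempted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "validate_weight_table",
    "harmonize",
    "align_positive",
    "compute_pgs",
    "HarmonizationError",
]

log = logging.getLogger(__name__)

_VALID_ALLELES = {"A", "C", "G", "T"}

REQUIRED_COLUMNS = ["id", "effect_allele", "other_allele", "beta", "eaf"]


class HarmonizationError(ValueError):
    """No variants survived harmonization."""


def validate_weight_table(weights: pd.DataFrame) -> pd.DataFrame:
    """Check the GWAS weight table contract; drops multi-allelic rows."""
    missing = [c for c in REQUIRED_COLUMNS if c not in weights.columns]
    if missing:
        raise ValueError(f"weight table missing required columns: {missing}")
    if weights["id"].duplicated().any():
        raise ValueError("variant ids in the weight table must be unique")
    ok = weights["effect_allele"].isin(_VALID_ALLELES) & weights["other_allele"].isin(
        _VALID_ALLELES
    )
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("dropping %d row(s) with non-single-base alleles", n_bad)
    return weights.loc[ok].copy()


def _folded_maf(freq: np.ndarray) -> np.ndarray:
    return np.minimum(freq, 1.0 - freq)


def harmonize(weights: pd.DataFrame, genotypes, maf_tol: float = 0.1):
    """Match GWAS weights to cohort variants.

    Returns ``(harmonized, actions)``. ``harmonized`` carries the original
    columns plus ``flip`` (score with dosage 2 - d) and ``cohort_freq``;
    ``actions`` has one row per input variant with its action in
    {keep, swap, drop} and a drop reason. Deterministic and independent of
    variant order. Raises :class:`HarmonizationError` if nothing survives.
    """
    weights = validate_weight_table(weights)
    gvar = genotypes.variants.set_index("id")
    actions = []
    kept = []
    for row in weights.itertuples(index=False):
        if row.id not in gvar.index:
            actions.append((row.id, "drop", "not_in_cohort"))
            continue
        g = gvar.loc[row.id]
        pair = (row.effect_allele, row.other_allele)
        g_pair = (g["effect_allele"], g["other_allele"])
        if pair == g_pair:
            action, flip = "keep", False
            cohort_ea_freq = g["frequency"]
        elif pair == (g_pair[1], g_pair[0]):
            action, flip = "swap", True
            cohort_ea_freq = 1.0 - g["frequency"]
        else:
            actions.append((row.id, "drop", "allele_mismatch"))
            continue
        if abs(_folded_maf(np.array(row.eaf)) - _folded_maf(np.array(g["frequency"]))) > maf_tol:
            actions.append((row.id, "drop", "maf_mismatch"))
            continue
        actions.append((row.id, action, ""))
        kept.append(
            {
                "id": row.id,
                "effect_allele": row.effect_allele,
                "other_allele": row.other_allele,
                "beta": row.beta,
                "eaf": row.eaf,
                "flip": flip,
                "cohort_freq": float(cohort_ea_freq),
            }
        )
    actions = pd.DataFrame(actions, columns=["id", "action", "reason"])
    if not kept:
        raise HarmonizationError("zero variants survived harmonization")
    harmonized = pd.DataFrame(kept).sort_values("id", kind="mergesort").reset_index(drop=True)
    return harmonized, actions


def align_positive(weights: pd.DataFrame) -> pd.DataFrame:
    """Flip rows so every effect size is positive.

    A negative effect is re-expressed on the other allele: alleles are
    swapped, the effect negated, frequencies complemented, and the dosage
    orientation (``flip``) toggled. Zero-effect rows are dropped with a
    warning. Individual-level score rankings are unchanged (the flip adds
    a per-individual constant).
    """
    out = weights.copy()
    zero = out["beta"] == 0.0
    if zero.any():
        log.warning("dropping %d variant(s) with zero effect size", int(zero.sum()))
        out = out.loc[~zero].copy()
    neg = out["beta"] < 0
    ea = out.loc[neg, "effect_allele"].copy()
    out.loc[neg, "effect_allele"] = out.loc[neg, "other_allele"].to_numpy()
    out.loc[neg, "other_allele"] = ea.to_numpy()
    out.loc[neg, "beta"] = -out.loc[neg, "beta"]
    out.loc[neg, "eaf"] = 1.0 - out.loc[neg, "eaf"]
    if "cohort_freq" in out.columns:
        out.loc[neg, "cohort_freq"] = 1.0 - out.loc[neg, "cohort_freq"]
    if "flip" in out.columns:
        out.loc[neg, "flip"] = ~out.loc[neg, "flip"].astype(bool)
    else:
        out["flip"] = neg
    return out


def compute_pgs(weights: pd.DataFrame, genotypes) -> tuple[pd.Series, int]:
    """Weighted sum of score-allele dosages per individual.

    Missing dosages contribute the variant's expected dosage
    (2 x score-allele frequency in the cohort), logged per variant.
    Returns ``(scores, n_variants_used)``.
    """
    gvar_idx = {vid: j for j, vid in enumerate(genotypes.variants["id"])}
    cols = []
    betas = []
    for row in weights.itertuples(index=False):
        j = gvar_idx.get(row.id)
        if j is None:
            log.warning("variant %s absent from genotypes, skipped", row.id)
            continue
        d = genotypes.dosages[:, j].astype(float)
        if getattr(row, "flip", False):
            d = 2.0 - d
        freq = getattr(row, "cohort_freq", np.nan)
        if np.isnan(d).any():
            fill = 2.0 * freq if np.isfinite(freq) else np.nanmean(d)
            n_miss = int(np.isnan(d).sum())
            log.info("variant %s: %d missing dosage(s) imputed to %.4f", row.id, n_miss, fill)
            d = np.where(np.isnan(d), fill, d)
        cols.append(d)
        betas.append(row.beta)
    if not cols:
        raise HarmonizationError("no variants available for scoring")
    score = np.column_stack(cols) @ np.asarray(betas)
    return pd.Series(score, index=genotypes.sample_ids, name="pgs"), len(cols)
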