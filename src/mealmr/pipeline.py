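"""End-to-end orchestration: QC -> response -> transform -> PGS ->
observational -> MR -> multiplicity -> comparisons, with the study's
analysis variants (weighted primary, unweighted, per-subpopulation,
per-sex, untransformed, extra covariables)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparisons, mr, multiplicity, observational, pgs, qc, response, transforms
from .simulate import GenotypeDosage, SynthConfig, SyntheticData, generate_cohort

__all__ = [
    "RunConfig",
    "ANALYSIS_TAGS",
    "run_pipeline",
    "run_sensitivity_suite",
    "write_inputs",
    "read_inputs",
    "read_flat_config",
]

log = logging.getLogger(__name__)

ANALYSIS_TAGS = (
    "weighted",
    "unweighted",
    "subpop_random",
    "subpop_oversampled",
    "female",
    "male",
    "untransformed",
    "extra_covariables",
)

_FLOAT_FMT = "%.12g"  # >= 10 significant digits in every TSV


@dataclass(frozen=True)
class RunConfig:
    """One analysis run: exactly one analysis_tag plus module parameters."""

    analysis_tag: str = "weighted"
    iqr_k: float = 10.0
    bivar_k: float = 10.0
    sample_missing_max: float = 0.2
    feature_missing_max: float = 0.2
    response_method: str = "deming"
    deming_lambda: float = 1.0
    rint_offset: float = 0.375
    tie_seed: int = 0
    maf_tol: float = 0.1
    cut_height: float = 0.5
    cluster_linkage: str = "average"
    cluster_corr: str = "spearman"
    alpha: float = 0.05
    extra_covariates: tuple = ()
    min_subset_n: int = 50

    def __post_init__(self):
        if self.analysis_tag not in ANALYSIS_TAGS:
            raise ValueError(f"analysis_tag must be one of {ANALYSIS_TAGS}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subset(data: SyntheticData, tag: str):
    """Rows, weighting, transform, covariates for one analysis variant."""
    cohort = data.cohort
    use_weights, transform = True, True
    covariates = list(observational.DEFAULT_COVARIATES)
    if tag == "unweighted":
        use_weights = False
    elif tag == "subpop_random":
        cohort = cohort[cohort["subpopulation"] == "random"]
        use_weights = False
        covariates = [c for c in covariates if c != "subpopulation"]
    elif tag == "subpop_oversampled":
        cohort = cohort[cohort["subpopulation"] == "oversampled"]
        use_weights = False
        covariates = [c for c in covariates if c != "subpopulation"]
    elif tag == "female":
        cohort = cohort[cohort["sex"] == "female"]
        covariates = [c for c in covariates if c != "sex"]
    elif tag == "male":
        cohort = cohort[cohort["sex"] == "male"]
        covariates = [c for c in covariates if c != "sex"]
    elif tag == "untransformed":
        transform = False
    return cohort, use_weights, transform, covariates


def run_pipeline(data: SyntheticData, cfg: RunConfig = RunConfig(), outdir=None) -> dict:
    """Execute the full analysis for one variant; returns a results bundle.

    Bundle keys: observational/mr (dict state -> estimate table), qc_report,
    response_fits, n_effective, threshold, comparisons, manifest.
    """
    cohort, use_weights, transform, covariates = _subset(data, cfg.analysis_tag)
    if cfg.analysis_tag == "extra_covariables":
        covariates = covariates + list(cfg.extra_covariates)
    ids = cohort["individual_id"]
    missing_geno = set(ids) - set(data.genotypes.sample_ids)
    if missing_geno:
        raise ValueError(
            f"id mismatch between genotype and phenotype tables; offenders: {sorted(missing_geno)[:10]}"
        )
    fasting = data.fasting.loc[data.fasting.index.intersection(ids)]
    postprandial = data.postprandial.loc[fasting.index]

    counts = {"individuals_in": int(len(cohort)), "traits_in": int(fasting.shape[1])}
    fast_qc, post_qc, qc_report = qc.run_qc(
        fasting,
        postprandial,
        iqr_k=cfg.iqr_k,
        bivar_k=cfg.bivar_k,
        sample_missing_max=cfg.sample_missing_max,
        feature_missing_max=cfg.feature_missing_max,
    )
    counts["individuals_after_qc"] = int(len(fast_qc))
    counts["traits_after_qc"] = int(fast_qc.shape[1])
    counts["individuals_removed_qc"] = counts["individuals_in"] - counts["individuals_after_qc"]

    resp, fits = response.build_response_matrix(
        fast_qc, post_qc, method=cfg.response_method, lam=cfg.deming_lambda
    )

    states = {"fasting": fast_qc, "postprandial": post_qc, "response": resp}
    if transform:
        states = {
            name: transforms.rint_matrix(m, seed=cfg.tie_seed, offset=cfg.rint_offset)
            for name, m in states.items()
        }

    harmonized, actions = pgs.harmonize(data.gwas_weights, data.genotypes, maf_tol=cfg.maf_tol)
    aligned = pgs.align_positive(harmonized)
    scores, n_used = pgs.compute_pgs(aligned, data.genotypes)
    cohort = cohort.copy()
    cohort["pgs"] = scores.reindex(cohort["individual_id"]).to_numpy()

    obs_tables, mr_tables = {}, {}
    for state, matrix in states.items():
        obs_tables[state] = observational.association_scan(
            matrix, cohort, state, use_weights=use_weights, covariates=covariates,
            analysis_tag=cfg.analysis_tag,
        )
        mr_tables[state] = mr.mr_scan(
            matrix, cohort, state, use_weights=use_weights, covariates=covariates,
            analysis_tag=cfg.analysis_tag,
        )

    pooled = pd.concat(
        {name: m for name, m in states.items()}, axis=1
    )
    pooled.columns = [f"{t}_{s[0]}" for s, t in pooled.columns]
    cluster = multiplicity.pv_cluster(
        pooled, cut_height=cfg.cut_height, linkage=cfg.cluster_linkage, corr=cfg.cluster_corr
    )
    threshold = multiplicity.bonferroni_threshold(cfg.alpha, cluster.n_effective)

    n_traits = fast_qc.shape[1]
    comp = {
        "fasting_vs_postprandial": comparisons.compare_tables(
            obs_tables["fasting"], obs_tables["postprandial"], "state-pair", cfg.alpha / max(n_traits, 1)
        ),
        "obs_vs_mr": {
            state: comparisons.estimate_vector_comparison(
                obs_tables[state], mr_tables[state], beta_a="beta", beta_b="beta_iv"
            )
            for state in states
            if len(obs_tables[state]) >= 3 and len(mr_tables[state]) >= 3
        },
    }

    manifest = {
        "analysis_tag": cfg.analysis_tag,
        "config_digest": cfg.digest(),
        "tie_seed": cfg.tie_seed,
        "use_weights": use_weights,
        "transform": transform,
        "covariates": covariates,
        "n_variants_scored": int(n_used),
        "n_effective": int(cluster.n_effective),
        "bonferroni_threshold": threshold,
        "counts": counts,
    }
    bundle = {
        "observational": obs_tables,
        "mr": mr_tables,
        "qc_report": qc_report,
        "response_fits": fits,
        "pgs_actions": actions,
        "cluster": cluster,
        "n_effective": cluster.n_effective,
        "threshold": threshold,
        "comparisons": comp,
        "manifest": manifest,
        "cohort": cohort,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def run_sensitivity_suite(
    data: SyntheticData,
    base_cfg: RunConfig = RunConfig(),
    tags=("weighted", "unweighted", "subpop_random", "subpop_oversampled", "female", "male", "untransformed"),
) -> dict:
    """Primary run plus every variant, with beta-vector comparisons to the
    primary. Variants whose subset is smaller than ``min_subset_n`` are
    skipped with a warning."""
    results = {}
    primary = run_pipeline(data, replace(base_cfg, analysis_tag="weighted"))
    results["weighted"] = primary
    cross = []
    for tag in tags:
        if tag == "weighted":
            continue
        cohort, *_ = _subset(data, tag)
        if len(cohort) < base_cfg.min_subset_n:
            log.warning("variant %s skipped: n = %d < %d", tag, len(cohort), base_cfg.min_subset_n)
            continue
        res = run_pipeline(data, replace(base_cfg, analysis_tag=tag))
        results[tag] = res
        for state in ("fasting", "postprandial", "response"):
            try:
                cmp_obs = comparisons.estimate_vector_comparison(
                    results["weighted"]["observational"][state], res["observational"][state]
                )
            except ValueError:
                continue
            cross.append({"variant": tag, "state": state, "framework": "observational", **cmp_obs})
    results["cross_run_comparison"] = pd.DataFrame(cross)
    return results


# ---------------------------------------------------------------------------
# File interfaces


def _write_tsv(df: pd.DataFrame, path: Path, index=False):
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def write_inputs(data: SyntheticData, outdir) -> dict:
    """Serialize a synthetic study to TSV inputs (phenotypes, dosages,
    variant info, GWAS weights, state matrices)."""
    outdir = Path(outdir)
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "dosages": outdir / "dosages.tsv",
        "variants": outdir / "variants.tsv",
        "gwas_weights": outdir / "gwas_weights.tsv",
        "fasting": outdir / "fasting.tsv",
        "postprandial": outdir / "postprandial.tsv",
    }
    pheno = data.cohort.drop(columns=[c for c in data.cohort.columns if c.startswith("_")])
    _write_tsv(pheno, paths["phenotypes"])
    dos = pd.DataFrame(
        data.genotypes.dosages, index=data.genotypes.sample_ids, columns=data.genotypes.variants["id"]
    )
    _write_tsv(dos.rename_axis("individual_id"), paths["dosages"], index=True)
    _write_tsv(data.genotypes.variants, paths["variants"])
    _write_tsv(data.gwas_weights.drop(columns=["beta_true"], errors="ignore"), paths["gwas_weights"])
    _write_tsv(data.fasting.rename_axis("individual_id"), paths["fasting"], index=True)
    _write_tsv(data.postprandial.rename_axis("individual_id"), paths["postprandial"], index=True)
    return paths


def read_inputs(indir) -> SyntheticData:
    """Load a study previously written by :func:`write_inputs`."""
    indir = Path(indir)
    cohort = pd.read_csv(indir / "phenotypes.tsv", sep="\t")
    dos = pd.read_csv(indir / "dosages.tsv", sep="\t", index_col="individual_id")
    variants = pd.read_csv(indir / "variants.tsv", sep="\t")
    gwas = pd.read_csv(indir / "gwas_weights.tsv", sep="\t")
    fasting = pd.read_csv(indir / "fasting.tsv", sep="\t", index_col="individual_id")
    postprandial = pd.read_csv(indir / "postprandial.tsv", sep="\t", index_col="individual_id")
    genotypes = GenotypeDosage(
        variants=variants, dosages=dos.to_numpy(dtype=float), sample_ids=dos.index.tolist()
    )
    mismatch = set(cohort["individual_id"]) ^ set(dos.index)
    if mismatch:
        raise ValueError(
            f"id mismatch between genotype and phenotype files; offenders: {sorted(mismatch)[:10]}"
        )
    return SyntheticData(
        cohort=cohort,
        genotypes=genotypes,
        gwas_weights=gwas,
        fasting=fasting,
        postprandial=postprandial,
        truth=pd.DataFrame(),
        config=None,
    )


def read_flat_config(path) -> dict:
    """Flat key = value config file; '#' starts a comment."""
    out = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        for cast in (int, float):
            try:
                val = cast(val)
                break
            except ValueError:
                continue
        out[key] = val
    return out


def simulate_from_config(params: dict) -> SyntheticData:
    known = set(SynthConfig.__dataclass_fields__)
    return generate_cohort(SynthConfig(**{k: v for k, v in params.items() if k in known}))


def _write_bundle(bundle: dict, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    tag = bundle["manifest"]["analysis_tag"]
    for framework in ("observational", "mr"):
        for state, table in bundle[framework].items():
            _write_tsv(table, outdir / f"{framework}_{state}_{tag}.tsv")
    _write_tsv(bundle["response_fits"], outdir / f"response_fits_{tag}.tsv")
    _write_tsv(bundle["qc_report"].to_frame(), outdir / f"qc_report_{tag}.tsv")
    _write_tsv(
        bundle["cluster"].assignments.rename_axis("trait").reset_index(),
        outdir / f"clusters_{tag}.tsv",
    )
    _write_tsv(bundle["comparisons"]["fasting_vs_postprandial"], outdir / f"ztests_{tag}.tsv")
    (outdir / f"manifest_{tag}.json").write_text(json.dumps(bundle["manifest"], indent=2))
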