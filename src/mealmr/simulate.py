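"""Synthetic cohorts with the structure the downstream analysis assumes.

The generator emulates a two-subpopulation meal-challenge study: one
stratum sampled at random, one oversampled for BMI above a threshold;
BMI is driven by a polygenic score, a sampling-date trend, age/sex, and
noise; paired fasting/postprandial metabolite matrices carry configurable
BMI effects on the fasting level, the postprandial level, and the
meal response. Everything is deterministic under a fixed config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "GenotypeDosage",
    "SyntheticData",
    "generate_genotypes",
    "generate_weight_table",
    "true_pgs",
    "make_skeleton",
    "generate_bmi",
    "generate_metabolites",
    "derive_sample_weights",
    "inject_missing_and_outliers",
    "generate_cohort",
]

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

# rng stream tags, so standalone calls and generate_cohort agree
_TAG_GENO, _TAG_WEIGHTS, _TAG_BMI, _TAG_METAB, _TAG_INJECT = 11, 13, 17, 19, 23


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study design.

    ``beta_fasting``/``beta_postprandial``/``beta_response`` are BMI effect
    sizes in trait-SD units per BMI unit; each may be a scalar (applied to
    all traits) or a sequence of length ``n_metabolites``.
    """

    n_random: int = 1400
    n_oversampled: int = 4100
    oversample_threshold: float = 27.0
    n_snps: int = 646
    maf_range: tuple = (0.05, 0.5)
    pgs_variance_explained: float = 0.045
    n_metabolites: int = 229
    n_classes: int = 14
    beta_fasting: object = 0.0
    beta_postprandial: object = 0.0
    beta_response: object = 0.0
    date_structure_r2: float = 0.20
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    seed: int = 0
    # secondary knobs
    bmi_mean: float = 26.0
    bmi_sd: float = 4.0
    agesex_r2: float = 0.01
    class_loading: float = 0.5
    passthrough_slope: float = 0.8
    female_fraction: float = 0.52
    weight_swap_fraction: float = 0.2
    min_noise_var: float = 0.05
    # optional structure for diagnostic tests
    date_confounding_beta: float = 0.0  # direct date effect on metabolite traits
    confounder_r2: float = 0.0  # hidden-confounder share of BMI variance
    beta_confounder: float = 0.0  # hidden-confounder effect on metabolite traits

    def __post_init__(self):
        for name in ("n_random", "n_oversampled", "n_snps", "n_metabolites", "n_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in (
            "pgs_variance_explained",
            "date_structure_r2",
            "agesex_r2",
            "confounder_r2",
            "missing_rate",
            "outlier_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if (
            self.pgs_variance_explained
            + self.date_structure_r2
            + self.agesex_r2
            + self.confounder_r2
        ) >= 1.0:
            raise ValueError("BMI variance fractions must sum to < 1")

    @property
    def n_total(self) -> int:
        return self.n_random + self.n_oversampled

    def beta_arrays(self):
        """Per-trait effect arrays broadcast from the scalar/sequence fields."""
        out = []
        for val in (self.beta_fasting, self.beta_postprandial, self.beta_response):
            arr = np.broadcast_to(np.asarray(val, dtype=float), (self.n_metabolites,))
            out.append(np.array(arr))
        return out


@dataclass
class GenotypeDosage:
    """Individuals x variants dosage matrix plus variant metadata.

    ``variants`` has columns id/effect_allele/other_allele/frequency;
    ``dosages`` is an (n_individuals, n_variants) float array in [0, 2].
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list

    def __post_init__(self):
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError("dosage matrix shape does not match metadata")
        if self.variants["id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        if np.nanmin(self.dosages) < 0 or np.nanmax(self.dosages) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    def reordered(self, order) -> "GenotypeDosage":
        ids = [self.sample_ids[i] for i in order]
        return GenotypeDosage(self.variants, self.dosages[np.asarray(order)], ids)


@dataclass
class SyntheticData:
    """Bundle returned by :func:`generate_cohort`."""

    cohort: pd.DataFrame
    genotypes: GenotypeDosage
    gwas_weights: pd.DataFrame
    fasting: pd.DataFrame
    postprandial: pd.DataFrame
    truth: pd.DataFrame
    config: SynthConfig = field(repr=False, default=None)
    injections: pd.DataFrame | None = None


def _rng(cfg: SynthConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def generate_genotypes(cfg: SynthConfig, n: int | None = None) -> GenotypeDosage:
    """Continuous dosages mimicking imputed data.

    Per variant, dosage = Binomial(2, maf) plus a small uniform jitter,
    clipped to [0, 2]. ``frequency`` records the nominal effect-allele
    frequency (= the sampling maf).
    """
    rng = _rng(cfg, _TAG_GENO)
    if n is None:
        n = cfg.n_total
    m = cfg.n_snps
    lo, hi = cfg.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    allele_idx = np.array([rng.choice(4, size=2, replace=False) for _ in range(m)])
    variants = pd.DataFrame(
        {
            "id": [f"rs{100000 + j}" for j in range(m)],
            "effect_allele": _BASES[allele_idx[:, 0]],
            "other_allele": _BASES[allele_idx[:, 1]],
            "frequency": mafs,
        }
    )
    hard = rng.binomial(2, mafs, size=(n, m)).astype(float)
    jitter = rng.uniform(-0.05, 0.05, size=(n, m))
    dosages = np.clip(hard + jitter, 0.0, 2.0)
    sample_ids = [f"id{i:06d}" for i in range(n)]
    return GenotypeDosage(variants=variants, dosages=dosages, sample_ids=sample_ids)


def generate_weight_table(cfg: SynthConfig, genotypes: GenotypeDosage) -> pd.DataFrame:
    """GWAS-style weight table for the variants in ``genotypes``.

    True effects are drawn oriented to the genotype effect allele; a
    fraction of emitted rows present the swapped-allele representation
    (beta negated, alleles exchanged, frequency flipped) so that
    harmonization has real work to do. Column ``beta_true`` keeps the
    genotype-oriented effect for truth bookkeeping.
    """
    rng = _rng(cfg, _TAG_WEIGHTS)
    m = len(genotypes.variants)
    beta_true = rng.normal(0.0, 0.03, size=m)
    beta_true[np.abs(beta_true) < 1e-4] += 0.01  # avoid exact zeros
    eaf = np.clip(
        genotypes.variants["frequency"].to_numpy() + rng.normal(0, 0.01, size=m), 0.01, 0.99
    )
    swap = rng.random(m) < cfg.weight_swap_fraction
    tbl = pd.DataFrame(
        {
            "id": genotypes.variants["id"].to_numpy(),
            "effect_allele": genotypes.variants["effect_allele"].to_numpy(),
            "other_allele": genotypes.variants["other_allele"].to_numpy(),
            "beta": beta_true,
            "eaf": eaf,
            "beta_true": beta_true,
        }
    )
    ea = tbl.loc[swap, "effect_allele"].copy()
    tbl.loc[swap, "effect_allele"] = tbl.loc[swap, "other_allele"].to_numpy()
    tbl.loc[swap, "other_allele"] = ea.to_numpy()
    tbl.loc[swap, "beta"] = -tbl.loc[swap, "beta"]
    tbl.loc[swap, "eaf"] = 1.0 - tbl.loc[swap, "eaf"]
    return tbl


def true_pgs(genotypes: GenotypeDosage, weights: pd.DataFrame) -> np.ndarray:
    """Polygenic score using the generator's genotype-oriented true effects."""
    w = weights.set_index("id").loc[genotypes.variants["id"], "beta_true"].to_numpy()
    return genotypes.dosages @ w


def make_skeleton(cfg: SynthConfig) -> pd.DataFrame:
    """Row-per-individual frame with ids and subpopulation labels."""
    n = cfg.n_total
    sub = np.array(["random"] * cfg.n_random + ["oversampled"] * cfg.n_oversampled)
    return pd.DataFrame({"individual_id": [f"id{i:06d}" for i in range(n)], "subpopulation": sub})


def _draw_environment(rng, n, subpop_is_oversampled, cfg):
    """Non-genetic BMI components for n individuals of one subpopulation."""
    if subpop_is_oversampled:
        date = rng.uniform(0.0, 1400.0, n)
    else:
        date = rng.uniform(900.0, 1400.0, n)  # random stratum sampled late
    date_z = (date - 700.0) / 404.0  # approx standardized over the design
    age = rng.uniform(45.0, 65.0, n)
    sex_female = rng.random(n) < cfg.female_fraction
    agesex_z = 0.5 * (age - 55.0) / 5.77 + 0.8 * (~sex_female - 0.48)
    agesex_z = agesex_z / np.sqrt(0.25 + 0.64 * 0.48 * 0.52)
    conf = rng.normal(size=n)
    eps = rng.normal(size=n)
    return date, date_z, age, sex_female, agesex_z, conf, eps


def _compose_bmi(pgs_z, date_z, agesex_z, conf, eps, cfg, pgs_scale):
    resid_frac = 1.0 - (
        cfg.pgs_variance_explained + cfg.date_structure_r2 + cfg.agesex_r2 + cfg.confounder_r2
    )
    # negative date trend: the late-sampled random stratum has lower BMI,
    # so the within-stratum trend reinforces the between-strata composition
    z = (
        pgs_scale * np.sqrt(cfg.pgs_variance_explained) * pgs_z
        - np.sqrt(cfg.date_structure_r2) * date_z
        + np.sqrt(cfg.agesex_r2) * agesex_z
        + np.sqrt(cfg.confounder_r2) * conf
        + np.sqrt(resid_frac) * eps
    )
    return cfg.bmi_mean + cfg.bmi_sd * z


def _generate_bmi_once(skeleton, pgs_z, cfg, seed_tag):
    """One deterministic cohort realization for a given PGS inflation factor.

    Returns a frame with environment columns; oversampled rows have their
    non-genetic components redrawn until BMI exceeds the threshold.
    """

    def build(pgs_scale):
        rng = np.random.default_rng([cfg.seed, seed_tag])
        is_over = (skeleton["subpopulation"] == "oversampled").to_numpy()
        n = len(skeleton)
        date = np.empty(n)
        date_z = np.empty(n)
        age = np.empty(n)
        female = np.empty(n, dtype=bool)
        conf = np.empty(n)
        bmi = np.empty(n)
        for oversampled in (False, True):
            sel = np.flatnonzero(is_over == oversampled)
            d, dz, a, f, az, c, e = _draw_environment(rng, sel.size, oversampled, cfg)
            b = _compose_bmi(pgs_z[sel], dz, az, c, e, cfg, pgs_scale)
            if oversampled:
                for _ in range(2000):
                    bad = b <= cfg.oversample_threshold
                    if not bad.any():
                        break
                    m = int(bad.sum())
                    d2, dz2, a2, f2, az2, c2, e2 = _draw_environment(rng, m, True, cfg)
                    d[bad], dz[bad], a[bad], f[bad], c[bad] = d2, dz2, a2, f2, c2
                    b[bad] = _compose_bmi(pgs_z[sel[bad]], dz2, az2, c2, e2, cfg, pgs_scale)
                else:  # pragma: no cover - astronomically unlikely at sane configs
                    raise RuntimeError("rejection sampling did not converge")
            date[sel], date_z[sel], age[sel], female[sel], conf[sel], bmi[sel] = (
                d,
                dz,
                a,
                f,
                c,
                b,
            )
        return date, date_z, age, female, conf, bmi

    return build


def generate_bmi(
    skeleton: pd.DataFrame,
    genotypes: GenotypeDosage,
    weights: pd.DataFrame,
    cfg: SynthConfig,
) -> pd.DataFrame:
    """Cohort table with BMI generated from the PGS -> BMI causal chain.

    The polygenic term is calibrated by fixed-point iteration (against the
    same random draws) so that the realized cohort-level regression of BMI
    on the true PGS explains ``cfg.pgs_variance_explained`` of the
    variance despite the selection applied to the oversampled stratum.

    Rows are ordered by visit date within each subpopulation batch; column
    ``genotype_row`` maps each row back to its row in ``genotypes``.
    """
    if len(skeleton) != len(genotypes.sample_ids):
        raise ValueError("skeleton and genotype row counts differ")
    if cfg.pgs_variance_explained >= 1.0:
        raise ValueError("pgs_variance_explained must be < 1")
    raw = true_pgs(genotypes, weights)
    sd = raw.std()
    pgs_z = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)
    build = _generate_bmi_once(skeleton, pgs_z, cfg, _TAG_BMI)

    target = cfg.pgs_variance_explained
    scale = 1.0
    date = date_z = age = female = conf = bmi = None
    for _ in range(12):
        date, date_z, age, female, conf, bmi = build(scale)
        if target == 0.0:
            scale = 0.0
            date, date_z, age, female, conf, bmi = build(scale)
            break
        r2 = np.corrcoef(pgs_z, bmi)[0, 1] ** 2
        if abs(r2 - target) < 5e-4:
            break
        scale *= np.sqrt(target / max(r2, 1e-8))

    cohort = pd.DataFrame(
        {
            "individual_id": skeleton["individual_id"].to_numpy(),
            "subpopulation": skeleton["subpopulation"].to_numpy(),
            "visit_date": np.round(date).astype(int),
            "age": age,
            "sex": np.where(female, "female", "male"),
            "bmi": bmi,
            "sample_weight": 1.0,
            "pgs_true": raw,
            "_date_z": date_z,
            "_confounder": conf,
            "genotype_row": np.arange(len(skeleton)),
        }
    )
    # visit_date monotone nondecreasing within each subpopulation batch
    is_over = (cohort["subpopulation"] == "oversampled").to_numpy()
    dates = cohort["visit_date"].to_numpy()
    order = np.concatenate(
        [
            np.flatnonzero(~is_over)[np.argsort(dates[~is_over], kind="stable")],
            np.flatnonzero(is_over)[np.argsort(dates[is_over], kind="stable")],
        ]
    )
    return cohort.iloc[order].reset_index(drop=True)


def generate_metabolites(cohort: pd.DataFrame, cfg: SynthConfig):
    """Paired fasting/postprandial matrices with configured BMI effects.

    Per trait (class c = trait index mod ``n_classes``)::

        fasting      = 5 + beta_f * (BMI - mean) + scaled(class factor + noise)
        postprandial = 5 + s * (fasting - 5) + (beta_p + beta_r) * (BMI - mean) + noise

    Noise variances are scaled so each trait has approximately unit SD,
    keeping the configured betas on the SD-per-BMI-unit scale. Returns
    ``(fasting, postprandial, truth)`` where ``truth`` records per-trait
    effective effects on each analysis state.
    """
    if cohort["bmi"].isna().any():
        raise ValueError("cohort has missing BMI")
    rng = _rng(cfg, _TAG_METAB)
    n = len(cohort)
    k = cfg.n_metabolites
    beta_f, beta_p, beta_r = cfg.beta_arrays()
    direct = beta_p + beta_r
    bmi_c = cohort["bmi"].to_numpy() - cohort["bmi"].mean()
    var_b = bmi_c.var()
    classes = np.arange(k) % cfg.n_classes
    latent = rng.normal(size=(n, cfg.n_classes))
    ell = cfg.class_loading
    s = cfg.passthrough_slope

    e1 = rng.normal(size=(n, k))
    e2 = rng.normal(size=(n, k))
    base = ell * latent[:, classes] + np.sqrt(1.0 - ell**2) * e1  # unit variance
    noise_var_f = np.maximum(1.0 - beta_f**2 * var_b, cfg.min_noise_var)
    fast_raw = beta_f * bmi_c[:, None] + np.sqrt(noise_var_f) * base
    if cfg.date_confounding_beta:
        fast_raw = fast_raw + cfg.date_confounding_beta * cohort["_date_z"].to_numpy()[:, None]
    if cfg.beta_confounder:
        fast_raw = fast_raw + cfg.beta_confounder * cohort["_confounder"].to_numpy()[:, None]

    cov_fb = beta_f * var_b
    var_e2 = np.maximum(1.0 - (s**2 + direct**2 * var_b + 2 * s * direct * cov_fb), cfg.min_noise_var)
    post_raw = s * fast_raw + direct * bmi_c[:, None] + np.sqrt(var_e2) * e2

    traits = [f"met{j:04d}" for j in range(k)]
    idx = cohort["individual_id"]
    fasting = pd.DataFrame(5.0 + fast_raw, index=idx, columns=traits)
    postprandial = pd.DataFrame(5.0 + post_raw, index=idx, columns=traits)
    truth = pd.DataFrame(
        {
            "trait": traits,
            "metabolite_class": [f"class{c:02d}" for c in classes],
            "beta_fasting": beta_f,
            "beta_postprandial": s * beta_f + direct,
            "beta_response": direct,
            "passthrough_slope": s,
        }
    )
    return fasting, postprandial, truth


def derive_sample_weights(cohort: pd.DataFrame, n_bins: int = 20) -> pd.DataFrame:
    """Density-ratio sampling weights on BMI, by equal-count bins.

    Random-stratum weights are 1. For the oversampled stratum, each BMI
    bin (edges at random-stratum quantiles) gets weight
    (random-stratum density) / (oversampled-stratum density), then
    weights are renormalized to mean 1 within the stratum, so the
    weighted oversampled BMI histogram emulates the random stratum's.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    cohort = cohort.copy()
    is_over = cohort["subpopulation"] == "oversampled"
    rand_bmi = cohort.loc[~is_over, "bmi"].to_numpy()
    over_bmi = cohort.loc[is_over, "bmi"].to_numpy()
    if rand_bmi.size == 0 or over_bmi.size == 0:
        raise ValueError("both subpopulations must be nonempty")
    edges = np.quantile(rand_bmi, np.linspace(0.0, 1.0, n_bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    edges = np.unique(edges)
    p_rand, _ = np.histogram(rand_bmi, bins=edges)
    p_over, _ = np.histogram(over_bmi, bins=edges)
    p_rand = p_rand / p_rand.sum()
    p_over = p_over / p_over.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bin = np.where(p_over > 0, p_rand / np.where(p_over > 0, p_over, 1.0), 0.0)
    empty = (p_over == 0) & (p_rand > 0)
    if empty.any():
        log.warning(
            "%d BMI bin(s) empty in the oversampled stratum with nonzero "
            "random-stratum mass; weight set to 0 there",
            int(empty.sum()),
        )
    which = np.clip(np.digitize(over_bmi, edges) - 1, 0, len(w_bin) - 1)
    w = w_bin[which]
    mean_w = w.mean()
    if mean_w > 0:
        w = w / mean_w
    cohort.loc[~is_over, "sample_weight"] = 1.0
    cohort.loc[is_over, "sample_weight"] = w
    cohort.attrs["weight_bins"] = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "p_random": p_rand,
            "p_oversampled": p_over,
            "raw_weight": w_bin,
        }
    )
    return cohort


def inject_missing_and_outliers(matrix: pd.DataFrame, cfg: SynthConfig):
    """Plant missing cells and gross outliers; return bookkeeping.

    Gross outliers are placed at >= 12 IQR from the per-trait median so a
    10-IQR filter must flag every one of them. Returns ``(matrix,
    injections)`` where ``injections`` is a frame with columns
    individual_id/trait/kind in {"missing", "outlier"}.
    """
    rng = _rng(cfg, _TAG_INJECT)
    out = matrix.copy()
    records = []
    vals = out.to_numpy()
    n, k = vals.shape
    if cfg.outlier_rate > 0:
        med = np.nanmedian(vals, axis=0)
        q75, q25 = np.nanpercentile(vals, [75, 25], axis=0)
        iqr = q75 - q25
        mask = rng.random((n, k)) < cfg.outlier_rate
        mask &= iqr > 0
        rows, cols = np.nonzero(mask)
        signs = rng.choice([-1.0, 1.0], size=rows.size)
        mags = 12.0 + rng.exponential(3.0, size=rows.size)
        vals[rows, cols] = med[cols] + signs * mags * iqr[cols]
        for r, c in zip(rows, cols):
            records.append((out.index[r], out.columns[c], "outlier"))
    if cfg.missing_rate > 0:
        mask = rng.random((n, k)) < cfg.missing_rate
        rows, cols = np.nonzero(mask)
        vals[rows, cols] = np.nan
        for r, c in zip(rows, cols):
            records.append((out.index[r], out.columns[c], "missing"))
    out.iloc[:, :] = vals
    injections = pd.DataFrame(records, columns=["individual_id", "trait", "kind"])
    return out, injections


def generate_cohort(cfg: SynthConfig) -> SyntheticData:
    """Full synthetic study: genotypes, weights, cohort, metabolites.

    Genotype rows are reordered to match the (date-sorted) cohort rows,
    and sampling weights are derived, so the bundle is analysis-ready.
    """
    genotypes = generate_genotypes(cfg)
    gwas = generate_weight_table(cfg, genotypes)
    skeleton = make_skeleton(cfg)
    cohort = generate_bmi(skeleton, genotypes, gwas, cfg)
    genotypes = genotypes.reordered(cohort["genotype_row"].to_numpy())
    genotypes.sample_ids = cohort["individual_id"].tolist()
    cohort = cohort.drop(columns=["genotype_row"])
    cohort = derive_sample_weights(cohort)
    fasting, postprandial, truth = generate_metabolites(cohort, cfg)
    injections = None
    if cfg.missing_rate > 0 or cfg.outlier_rate > 0:
        fasting, inj_f = inject_missing_and_outliers(fasting, cfg)
        post_cfg = replace(cfg, seed=cfg.seed + 1)
        postprandial, inj_p = inject_missing_and_outliers(postprandial, post_cfg)
        injections = pd.concat(
            [inj_f.assign(state="fasting"), inj_p.assign(state="postprandial")],
            ignore_index=True,
        )
    return SyntheticData(
        cohort=cohort,
        genotypes=genotypes,
        gwas_weights=gwas,
        fasting=fasting,
        postprandial=postprandial,
        truth=truth,
        config=cfg,
        injections=injections,
    )
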