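# mealmr

Observational and one-sample Mendelian randomization (MR) analysis of how
body mass index (BMI) relates to metabolite traits in three dietary
states — fasting, postprandial, and meal response — built around a
meal-challenge cohort design with two subpopulations (one sampled at
random, one oversampled for high BMI) and density-ratio sampling weights.

Because the individual-level study data this design emulates are
access-restricted, the package ships a first-class synthetic-cohort
generator so every stage of the analysis is testable end to end.

## What's inside

| module | role |
| --- | --- |
| `mealmr.simulate` | synthetic cohorts: dosage genotypes, GWAS-style weight tables, PGS → BMI → metabolite causal chain, sampling-date structure, BMI-bin density-ratio weights, missing/outlier injection |
| `mealmr.qc` | metabolite cleaning: zeros → NA, 10-IQR univariate filter, bivariate fasting/postprandial screen (Deming-residual IQR), sample/feature missingness filters |
| `mealmr.response` | per-trait Deming (errors-in-both-variables) regression of postprandial on fasting; vertical residuals = response trait; simple delta alternative |
| `mealmr.pgs` | GWAS weight harmonization (keep/swap/drop with folded-MAF ±0.1 check), positive-effect alignment, weighted allele-dosage scoring |
| `mealmr.transforms` | rank-based inverse-normal transformation (random tie-breaking, Blom offset) and Shapiro–Wilk normality screening |
| `mealmr.observational` | weighted multivariable GLM (`metabolite ~ visit_date + subpopulation + age + sex + BMI`), Breusch–Pagan test, sequential (type I) η², paired fasting/postprandial descriptives, confounder screen |
| `mealmr.mr` | weighted two-stage least squares with the PGS as instrument: proper 2SLS variance, weak-instrument partial F, Durbin–Wu–Hausman endogeneity test |
| `mealmr.multiplicity` | effective number of independent tests via principal-variable clustering (1 − \|corr\| distance, tree cut, medoid representatives) and Bonferroni thresholds |
| `mealmr.comparisons` | z tests between estimate vectors (states, sexes, frameworks), Pearson/OLS vector comparison, shared/unique association classification, lipoprotein profile table |
| `mealmr.pipeline` | orchestration of the full analysis and its sensitivity variants (weighted primary, unweighted, per-subpopulation, per-sex, untransformed outcomes, extra covariables), TSV interfaces, flat-config parsing |

## CLI

`mealmr` exposes one subcommand per stage plus an end-to-end runner:

```sh
# generate a synthetic study (TSV inputs: phenotypes, dosages, variants,
# GWAS weights, fasting/postprandial matrices)
mealmr simulate --seed 1 --n-random 700 --n-oversampled 1300 \
    --n-snps 100 --n-metabolites 50 --out inputs/

# individual stages
mealmr qc --indir inputs/ --out qc/ --iqr-k 10 --bivar-k 10
mealmr respond --fasting qc/fasting_qc.tsv --postprandial qc/postprandial_qc.tsv --out resp/
mealmr pgs --indir inputs/ --out pgs/
mealmr assoc --indir inputs/ --matrix qc/fasting_qc.tsv --out obs_fasting.tsv
mealmr mr --indir inputs/ --matrix qc/fasting_qc.tsv --pgs-file pgs/pgs.tsv --out mr_fasting.tsv
mealmr cluster --matrix qc/fasting_qc.tsv --out clusters.tsv
mealmr compare --table-a obs_a.tsv --table-b obs_b.tsv --threshold 1.163e-3 --out ztests.tsv

# everything at once (QC -> response -> RINT -> PGS -> observational ->
# MR -> multiplicity -> comparisons), for any analysis variant
mealmr run-all --indir inputs/ --tag weighted --out results/
```

Configuration can also come from a flat `key = value` text file via
`--config`.

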