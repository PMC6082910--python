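# latentprs

Latent-variable analysis of polygenic risk and adolescent
psychopathology: ordinal confirmatory factor models, omega reliability,
and simultaneous latent-factor-on-PRS regression with permutation and
inverse-probability-weighting sensitivity analyses.

## The problem

Polygenic risk scores (PRSs) for psychiatric disorders predict many
adolescent outcomes at once, and the outcomes are heavily comorbid.
Regressing each questionnaire scale on a PRS separately confounds
disorder-specific genetic signal with what is shared across all scales,
and sum scores carry measurement error that attenuates small genetic
effects.  The latent-modelling approach implemented here addresses both:
ordinal items from several instruments are modelled as indicators of
latent factors, competing measurement structures are compared, and the
factors are regressed on standardized PRSs *inside* the measurement
model (a MIMIC design), so that a "general psychopathology" factor can
absorb shared variance while specific factors capture what remains.

The package is aimed at epidemiologists and psychiatric geneticists who
want this workflow as tested, scriptable Python rather than proprietary
SEM software, plus a seeded synthetic-cohort generator so every stage is
testable without access-controlled cohort data.

## The model

For item *j* with ordered categories, a latent standard-normal response
y\*ⱼ produces the observed category by thresholds τⱼ.  Four structures
for the latent responses are compared: four uncorrelated group factors,
one unidimensional factor, four correlated group factors, and a
bifactor model (general factor *g* on all items plus orthogonal
block-specific factors).  Estimation is WLSMV-style: polychoric
correlations + diagonally weighted least squares under the delta
parameterization, with a Satterthwaite mean-and-variance adjusted χ²,
RMSEA/CFI/TLI, and AIC/BIC/ssaBIC from a quasi-Monte-Carlo marginal
likelihood.  Reliability of the bifactor solution is summarised by
ω, ω_H and per-block ω_S, ω_HS.  The structural model regresses every
factor simultaneously on a standardized PRS; β is the SD change in
latent trait per SD of PRS, with sandwich standard errors.  Sensitivity
analyses: max-T step-down permutation-adjusted P-values on MAP factor
scores, and IPW for covariate-dependent inclusion.  PRS construction
(P-value thresholding, allele harmonisation, weighted allele sums,
standardisation) is built in.

See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from latentprs import (
    MeasurementModel, PolygenicScorer, compute_omegas, fit_structural,
    simulate_cohort, apply_inclusion_filter,
)

cohort = simulate_cohort(n=2000, n_snps=300, seed=7)   # bifactor truth
blocks = cohort.model.item_blocks

# respondents answering >= 4 items in every instrument block
items, report = apply_inclusion_filter(cohort.items, blocks)
print(report)                 # {'n_input': 2000, 'n_kept': 1227, ...}

mm = MeasurementModel(structure="bifactor", item_blocks=blocks).fit(items)
print(mm.fit_indices_.format_rmsea())     # 0.000 (0.000, 0.010)
print(round(mm.fit_indices_.cfi, 3))      # 1.0

om = compute_omegas(mm.result_)
print(round(om.omega_total, 2), round(om.omega_hierarchical, 2))  # 0.99 0.89

prs = PolygenicScorer(sumstats=cohort.summary_stats[0],
                      p_threshold=0.05).fit(cohort.genotypes)
z = prs.transform(cohort.genotypes).ravel()           # mean 0, SD 1
res = fit_structural(items, z[cohort.items.index.isin(items.index)],
                     "bifactor", item_blocks=blocks)
print(res.table.round(3))
#                  outcome   beta     se    lci    uci      p
# 0                GENERAL  0.081  0.040  0.003  0.160  0.043
# 1  psychotic_experiences -0.065  0.054 -0.171  0.042  0.233
# 2     negative_dimension -0.090  0.060 -0.208  0.027  0.132
# 3             depression -0.081  0.050 -0.179  0.017  0.104
# 4                anxiety -0.007  0.056 -0.116  0.102  0.901
```

A zero RMSEA / unit CFI says the bifactor structure reproduces the
polychoric correlations essentially exactly (it generated them);
ω_H = 0.89 says most total-score variance is due to the general factor;
and each β row is the standardized effect of the PRS on one latent
factor with its Wald CI — at n ≈ 1200 the true general-factor effect of
0.055 is estimated at 0.08 ± 0.04, a reminder that effects of this size
need thousands of respondents for stable inference.

The same workflow is scriptable from the shell:

```bash
latentprs simulate --n 2000 --seed 7 --out demo/
latentprs prs-score --sumstats demo/sumstats_trait1.tsv --geno demo/genotypes.tsv --out demo/prs/
latentprs measure-fit --items demo/items.csv --blocks demo/blocks.yaml --structure bifactor --out demo/fit/
latentprs assoc-run --items demo/items.csv --blocks demo/blocks.yaml --prs demo/prs/prs.csv --out demo/assoc/
```

or end to end from a YAML config with `latentprs pipeline`.

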