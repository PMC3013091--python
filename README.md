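# gci — Genetic Composite Index lifetime-risk estimation

`gci` estimates an individual's lifetime risk of a common chronic disease
from **summary statistics only**: per-SNP relative risks (or case-control
odds ratios) with genotype frequencies, optionally combined with categorical
environmental factors (BMI class, smoking status, ...).  It is aimed at
statistical geneticists and risk-model developers who need pre-symptomatic
risk scores for conditions — type 2 diabetes, Crohn's disease, rheumatoid
arthritis — where no single study has measured all risk factors jointly.

## The score

With `k` independent risk loci, the GCI lifetime-risk probability of
individual *i* is

```
GCI_i = Pr(D) · Π_j λ_ij / Π_j Σ_k λ_jk f_jk
```

where `Pr(D)` is the average lifetime risk (ALTR), `λ_ij` the relative risk
of individual *i*'s genotype at locus *j*, and the denominator is the
population-mean relative-risk product, so that `E[GCI] = Pr(D)` exactly
under linkage equilibrium.  The EGCI adds environmental factors as extra
"loci" with exposure categories in place of genotypes.

Around this score the package provides:

* **Odds-ratio → relative-risk conversion with diseased controls**
  (`gci.or2rr`).  On the lifetime scale an `α` fraction of a study's
  controls will eventually develop the disease.  Writing
  `x_i = Pr(D | genotype i)`, the observed odds ratio is
  `OR_i = (x_i/x_0) · c(x_0)/c(x_i)` with
  `c(x) = α·x/Pr(D) + (1−α)(1−x)/(1−Pr(D))`; a monotone bisection on `x_0`
  under the constraint `Σ f_i x_i = Pr(D)` recovers the penetrances.
  `α` can be supplied, estimated by maximum likelihood from the study
  counts, or derived from the control ages under a normal age-of-onset
  model.
* **Liability-threshold disease models** (`gci.liability`): phenotype
  `P = G + E`, disease iff `P > T`, heritability `h = Var(G)/Var(P)`.
  Model 1 is fully normal; model 2 splits `G` into explicit large-effect
  SNPs (`Σ λ_i X_i`, `X_i ~ Bin(2, p_i)`) plus a polygenic remainder, with
  the `λ_i` solved so the model's heterozygote relative risks match given
  targets.  Includes the *theoretical genetic maximum* AUC — the ceiling any
  genetics-only classifier can reach, a function of `(h, ALTR)` alone — and
  the inversion of an observed score AUC into the fraction of genetic
  variance explained.
* **Cohort simulators** (`gci.simulate`): multiplicative (EGCI-driven)
  cohorts, SNP-pair interaction cohorts whose joint risk is `γ×` the
  multiplicative prediction on chosen genotype combinations while marginal
  relative risks still match the published values, and age-matched
  case-control studies with uniform ages, normal onset and pre-onset
  diseased controls.
* **ROC/AUC evaluation and experiment drivers** (`gci.evaluate`), including
  a pairwise-interaction logistic-regression baseline.
* **Bundled summary tables** (`gci.core_io.load_fixtures`): the published
  13-SNP type 2 diabetes, 27-SNP Crohn's disease and 5-SNP rheumatoid
  arthritis panels, the GENEVA 15-SNP panel, environmental relative risks,
  and per-disease heritability / average lifetime risk.

## Worked example

```python
from gci import (
    load_fixtures, RiskProfile, gci_score, egci_score,
    calibrate_model1, theoretical_max_auc,
    ConversionProblem, solve_penetrances,
)

fixtures = load_fixtures()
markers, disease = fixtures["ra_table1"]          # rheumatoid arthritis panel

# an individual heterozygous at all five RA risk SNPs
profile = RiskProfile((1, 1, 1, 1, 1), tuple(markers), disease)
print(gci_score(profile))                          # 0.0171

# the same person, currently smoking
smoking = fixtures["ra_env"][0][0]
full = RiskProfile((1, 1, 1, 1, 1, smoking.levels.index("Current-Smoker")),
                   tuple(markers) + (smoking,), disease)
print(egci_score(full))                            # 0.0189

# ceiling for any genetics-only RA classifier (h=0.53, ALTR=1.54%)
print(theoretical_max_auc(calibrate_model1(disease), analytic=True))  # 0.938

# odds ratios (1, 1.5, 2.5) from a study whose controls are 10% future cases
sol = solve_penetrances(
    ConversionProblem((1.0, 1.5, 2.5), (0.25, 0.5, 0.25), altr=0.25,
                      alpha_controls=0.10))
print(sol.rel_risks)        # (1.0, 1.421, 2.142) — ORs overstate lifetime RRs
print(sol.p_d_given_level)  # (0.1671, 0.2375, 0.3580), mean = 0.25
```

The individual's five heterozygous risk genotypes raise their lifetime RA
risk from the population average of 1.54% to 1.71%, and current smoking to
1.89%.  The conversion example shows why odds ratios must not be used as
lifetime relative risks for common diseases: the OR of 2.5 corresponds to a
lifetime relative risk of only 2.14 once control contamination is accounted
for.

A `gci` command-line tool wraps the same functionality
(`gci convert`, `gci score`, `gci simulate`, `gci simulate-casecontrol`,
`gci theoretical-auc`, `gci solve-lambdas`, `gci evaluate`,
`gci reproduce`); see `gci --help`.

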