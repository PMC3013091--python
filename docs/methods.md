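# Methods

## The multiplicative lifetime-risk model

The package's central quantity is the lifetime disease probability of an
individual given their genotypes `g_1 … g_k` at independent risk loci.  By
Bayes' rule and locus independence,

    Pr(D | g_1 … g_k) = Pr(D) · Π_j [ Pr(D | g_j) / Pr(D) ]
                      = Pr(D) · Π_j λ_j(g_j) / Π_j E[λ_j],

where `λ_j(g)` is the lifetime relative risk of genotype `g` at locus `j`
versus the zero-risk-allele genotype, and `E[λ_j] = Σ_k λ_jk f_jk` its
frequency-weighted population mean.  The normalization by `Π E[λ_j]` is what
makes the score a calibrated probability: its population expectation equals
the average lifetime risk (ALTR) exactly, which the test suite verifies by
exhaustive enumeration over all `3^5` genotype combinations of the
rheumatoid-arthritis panel (tolerance 1e-10) and by Monte Carlo for the
27-SNP panel.  Environmental factors with categorical exposure levels enter
the identical formula as additional "loci" (EGCI).

Because the score is an unconstrained product of relative risks it can
exceed 1 for extreme profiles (a BMI ≥ 35 relative risk of 42.1 at ALTR 25%
does it on its own).  Scores are capped at 1; the uncapped value is
available (`cap=False`) because the *overshoot itself* is diagnostic — it is
how naive odds-ratio-based risk estimates advertise their own inflation.
Products are accumulated in log space so 30-marker panels cannot under- or
overflow.

Missing genotypes contribute relative risk 1 (the marker is skipped) and are
counted with a warning; the underlying publications do not address
missingness and this choice keeps the score's expectation interpretation.

## Odds ratios, relative risks and diseased controls

Case-control studies report odds ratios; the score needs lifetime relative
risks.  The two differ for common diseases, and additionally a fraction
`α ∈ [0, ALTR]` of any real study's controls will develop the disease later
in life.  With `x_i = Pr(D | a_i)` the per-level lifetime penetrance, the
control arm's level distribution is the mixture
`α·Pr(a_i|D) + (1−α)·Pr(a_i|¬D)`, giving

    OR_i = (x_i / x_0) · c(x_0) / c(x_i),
    c(x) = α·x/Pr(D) + (1−α)·(1−x)/(1−Pr(D)).

For a candidate baseline penetrance `x_0` each identity is *linear* in
`x_i`, so every non-baseline penetrance has a closed form and no nested
search is needed.  The population constraint `Σ f_i x_i = Pr(D)` is strictly
increasing in `x_0` (property-tested on 1,000 random problems), so a plain
bisection (absolute tolerance 1e-12, ≤ 200 iterations) finds the unique
root.  When all ORs are ≥ 1 the root lies in `(0, Pr(D))`; noisy estimated
ORs below 1 can push the baseline penetrance above `Pr(D)`, so the bracket
extends to `(0, 1)` in that case.  Useful limits, all tested: `α = ALTR`
(population controls) makes OR = lifetime RR exactly; `α = 0` recovers the
classical prevalence-based conversion; `ALTR → 0` makes OR → RR.

`α` itself can be supplied, profiled out by maximum likelihood (grid
pre-scan of 21 points on `[0, ALTR]` plus golden-section refinement of the
multinomial likelihood of the observed case/control level counts; a flat
profile returns the boundary with a degeneracy flag), or computed from the
control ages as `α = ALTR · mean_controls Pr(onset > age)` under a
Normal(onset mean, onset SD) age-of-onset model.  The age formula ignores
the mild selection effect of conditioning on "not yet an observed case";
the simulation tests quantify the approximation (≲ 15% relative for an
ALTR-25% disease with the default onset model) and show it is unbiased
enough to recover heterozygote relative risks from simulated studies.

## Liability-threshold models

Model 1: `P = G + E`, `G ~ N(0, σ_G²)`, `E ~ N(0, σ_E²)` independent,
disease iff `P > T`.  Calibration uses the canonical unit-total-variance
scale: `σ_G² = h`, `σ_E² = 1 − h`, `T = Φ⁻¹(1 − ALTR)`.  The ROC curve of a
classifier that knows `G` exactly — the *theoretical genetic maximum* — is
invariant to rescaling all three parameters by a common factor, so it
depends on `(h, ALTR)` only; the tests assert bit-identical AUCs under
rescaling by 0.1–10×.  An analytic mode evaluates the AUC by dense-grid
quadrature over `G` (40,001 points over ±9σ; agreement with simulation is
within Monte-Carlo error).

Model 2 adds explicit large-effect SNPs: `G = Σ_i λ_i X_i + G1` with
`X_i ~ Binomial(2, p_i)` and `G1 ~ N(0, σ_G1²)`, under the budget
`σ_G1² + Σ 2p_i(1−p_i)λ_i² = h`.  Given target heterozygote relative risks
`RN_i`, the `λ_i` are solved by coordinate-wise root-finding (Gauss–Seidel
sweeps in input order): for locus *i*, the distribution of
`z = Σ_{j≠i} λ_j X_j` is computed *exactly* by dynamic-programming
convolution of the per-locus three-atom distributions on a value grid
(resolution 1e-4 of the total liability SD, colliding atoms merged —
summing over all `3^27` genotype configurations verbatim is infeasible),
the threshold is re-solved at every candidate `λ_i` so the ALTR constraint
always holds (safeguarded Newton on the mixture survival function), and

    RN_i = Σ_z w(z)·Φ̄((T − z − λ_i)/s) / Σ_z w(z)·Φ̄((T − z)/s),
    s = sqrt(σ_G1² + σ_E²),

is matched by Brent's method on `[0, λ_max)` where `λ_max` exhausts the
remaining heritability.  The candidate locus's own atoms are deliberately
*not* re-rounded onto the grid, which keeps `RN_i(λ_i)` smooth for the
root-finder; convergence is declared when the largest residual
`|RN_implied − RN_target|` drops below 1e-6 (typically 2–4 sweeps; the
27-SNP panel solves in ~20 s).  Targets are heterozygote relative risks
only; homozygote effects follow from per-allele additivity in liability.
Unreachable targets (large-effect variance exceeding `h`) raise rather than
silently shrink.

Two routes to "fraction of genetic variance explained by known variants"
are provided, because the published procedure is ambiguous: (a) invert an
observed score AUC under model 1 by bisecting the variance of a known
liability component until its analytic AUC matches; (b) the model-2
large-effect variance ratio `Σ 2p_i(1−p_i)λ_i² / h` after solving for the
published panels.  On the bundled tables the two routes agree within ~35%
of each other (T2D 8.7% vs 5.8%, Crohn's 7.2% vs 8.3%, RA 11.6% vs 12.9%),
and both land within a factor of two of the published ~6%/9%/14%.

## Simulators

*Multiplicative cohorts.*  Genotypes and environmental levels are drawn
independently from their level frequencies (inverse-CDF on one uniform per
value); status is Bernoulli with probability equal to the capped EGCI score,
so the expected case fraction is the ALTR (conservation law tested at 3
binomial SEs for every simulator).

*Interaction cohorts.*  One SNP pair (default: the two markers with the
largest heterozygote relative risks) deviates from multiplicativity: joint
relative risk `γ · λ_x(g_x) λ_y(g_y)` on a boosted set of genotype
combinations (default: both SNPs carrying ≥ 1 risk allele — symmetric,
nonempty, solvable).  The four free pair parameters are re-solved in log
space (damped hybrid root-finder started at the published values) so the
*marginal* relative risks of each SNP still equal the published univariate
values — a single-SNP analysis of such a cohort reproduces its summary
table exactly, tested by independent 9-cell enumeration.  Case probabilities
are `λ_i / C`; `C = E[λ]/ALTR` uses the exact population expectation
(product of per-marker means times the 9-cell pair expectation) rather than
a Monte-Carlo estimate, which makes `γ = 1` reduce to the multiplicative
simulator draw-for-draw and keeps the case fraction calibrated in
expectation.

*Age-structured case-control studies.*  Individuals from model 2 receive
age ~ Uniform[0, 100]; lifetime-diseased individuals get onset ~
Normal(50, 13) truncated to [0, 100] by resampling, and are *observed*
cases only once past onset.  Each observed case is matched to one
not-yet-case control on integer (floored) age; a control is used at most
once, and matching draws fresh individuals in batches until satisfied
(bounded; matching exhaustion raises).  Controls therefore contain
pre-onset lifetime cases at exactly the rate the `α` machinery predicts.
Per-SNP odds ratios come from the 2×3 genotype tables with a 0.5 continuity
correction only when a cell is empty.

*Relative-error experiment.*  Odds ratios estimated from such a study are
converted to relative risks (with `α` from the control ages) or used raw,
and both are applied as multiplicative risk estimates to fresh individuals.
The error baseline is each individual's *correct genetic risk given their
genotypes at the modelled SNPs*, `Φ((λ·X − T)/sqrt(σ_G1² + σ_E²))` — the
quantity a genotype-based score estimates.  Conditioning instead on the full
liability including the unobservable polygenic term would swamp both
estimators in identical irreducible error (median ~0.76) and hide the
OR-vs-RR contrast the experiment exists to measure.  With the
genotype-conditional baseline the converted-RR estimates have median
absolute relative error ~0.03 against ~0.06–0.14 for raw ORs, and at ALTR
42% raw-OR estimates exceed 100% lifetime risk.

## Evaluation

The AUC point estimate is the tie-corrected Mann–Whitney rank statistic
(ties count ½), which equals the trapezoidal area under the all-thresholds
ROC curve to 1e-12; a 1,000-quantile-threshold grid mode mirrors coarser
published curves (within 0.002 of exact at n ≥ 10,000).  The
pairwise-interaction logistic baseline fits main effects plus all `s_i s_j`
products by maximum likelihood (statsmodels IRLS, tolerance 1e-8), dropping
constant columns with a warning and falling back to a 1e-6 ridge
(scikit-learn) on separation or non-convergence; it can score held-out
individuals so comparisons against the GCI are not distorted by in-sample
overfit (~90 free parameters on a 13-SNP panel inflate the training AUC by
~0.02 at n = 10,000).

## What the simulations do and do not show

The generators implement the generative assumptions of the score itself
(locus independence, multiplicative effects, known frequencies) or
controlled violations of them (the γ pair, liability model 2, age
structure).  Passing tests therefore demonstrate internal consistency and
robustness to the *modelled* deviations — not performance on real cohorts,
where linkage disequilibrium, population stratification, genotyping error
and secular incidence trends (all out of scope here) also operate.

Problem sizes follow the published experiments: cohorts of 100,000,
case-control studies of 10,000 cases with age matching, 500 fresh evaluation
individuals, 1,000,000-draw Monte-Carlo checks of the λ solver.  Where a
published AUC is compared at these sizes its seed-to-seed SD is ~0.01 for
the low-ALTR diseases, so acceptance tests average ten replicate cohorts to
compare generative processes rather than single draws.

## Known limitations

* The Crohn's disease GCI-vs-EGCI simulation reproduces the published
  pattern but not the exact printed AUCs (0.725/0.751 here vs 0.74/0.78):
  under the printed genotype frequencies several high-risk homozygote
  classes have frequency exactly 0 and are never drawn, and the AUC of this
  experiment is fully determined by the relative-risk product distribution
  those tables imply.  (Sampling from Hardy–Weinberg allele frequencies
  instead reproduces the rheumatoid-arthritis figures almost exactly but
  still not Crohn's.)  The type 2 diabetes driver uses BMI and smoking only;
  a third environmental factor named for that figure has no published
  levels.
* The incidence → lifetime-risk conversion is the steady-state ratio
  "annual new cases / annual births" under fixed population size and a
  universal maximal lifespan, pooled over strata; age-specific incidence
  curves and competing mortality are not modelled.
* `α` estimation assumes a single normal age-of-onset distribution shared
  by all genotypes.
* Environmental factor frequencies from the published tables are rescaled
  to sum to 1 (the printed proportions carry up to 1% rounding error).
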