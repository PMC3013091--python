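"""ROC/AUC evaluation and the simulation experiments.

The AUC point estimate is the tie-corrected rank (Mann-Whitney) statistic,
which equals the trapezoidal area under the all-thresholds ROC curve; a
1,000-point quantile-threshold grid mode exists to mirror coarser published
curves.  The experiment drivers reproduce the study designs end to end:

* ``experiment_optimal_auc`` — theoretical genetic maximum: AUC of the exact
  genetic liability under calibrated liability model 1;
* ``experiment_gci_vs_egci`` — simulate a cohort whose disease status is
  drawn from EGCI probabilities and compare the genetics-only GCI score with
  the full EGCI score;
* ``experiment_interaction_vs_multiplicative`` — simulate under a
  gamma-boosted SNP-pair model and compare the true interaction risk score
  with the multiplicative GCI score;
* ``experiment_relative_error`` — age-structured case-control study, odds
  ratios estimated, converted to lifetime relative risks (with the
  diseased-control correction) and applied to fresh individuals; the
  absolute relative errors of relative-risk-based versus raw-odds-ratio
  lifetime risk estimates are returned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core_io import DiseaseParams, load_fixtures
from .liability import (
    LiabilityModel2Spec,
    calibrate_model1,
    sample_model1,
    sample_model2,
    solve_lambdas_model2,
)
from .or2rr import ConversionProblem, alpha_from_ages, solve_penetrances
from .riskmodel import cohort_scores
from .simulate import (
    Cohort,
    assign_status_interaction,
    assign_status_multiplicative,
    interaction_relative_risks,
    simulate_age_structured_casecontrol,
    simulate_genotypes,
    solve_interaction_lambdas,
)

__all__ = [
    "ROCCurve",
    "roc_auc",
    "fit_logistic_pairwise",
    "experiment_optimal_auc",
    "experiment_gci_vs_egci",
    "experiment_interaction_vs_multiplicative",
    "experiment_relative_error",
    "RelativeErrorResult",
]


@dataclass
class ROCCurve:
    """FPF/TPF pairs over descending thresholds plus the AUC.

    ``auc`` is the tie-corrected rank statistic; ``trapezoid_auc`` is the
    trapezoidal area under this curve's points (identical in all-thresholds
    mode, approximate in grid mode).
    """

    thresholds: np.ndarray
    fpf: np.ndarray
    tpf: np.ndarray
    auc: float
    trapezoid_auc: float


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc(scores, labels, mode: str = "all-thresholds") -> ROCCurve:
    """ROC curve and AUC of a score against binary disease status.

    ``mode="all-thresholds"`` places a threshold at every distinct score
    (ties collapse to one point); ``mode="grid-1000"`` uses 1,000 equally
    spaced score quantiles.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(np.int8)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("need at least one case and one control")
    auc = _rank_auc(scores, labels)
    if mode == "all-thresholds":
        thresholds = np.unique(scores)[::-1]
    elif mode == "grid-1000":
        thresholds = np.quantile(scores, np.linspace(1.0, 0.0, 1000))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    case_scores = np.sort(scores[labels == 1])
    ctrl_scores = np.sort(scores[labels == 0])
    # score >= threshold is called positive
    tpf = 1.0 - np.searchsorted(case_scores, thresholds, side="left") / n1
    fpf = 1.0 - np.searchsorted(ctrl_scores, thresholds, side="left") / n0
    thresholds = np.concatenate(([np.inf], thresholds, [-np.inf]))
    tpf = np.concatenate(([0.0], tpf, [1.0]))
    fpf = np.concatenate(([0.0], fpf, [1.0]))
    trap = float(np.trapezoid(tpf, fpf))
    return ROCCurve(thresholds=thresholds, fpf=fpf, tpf=tpf, auc=auc, trapezoid_auc=trap)


def _pairwise_design(values: np.ndarray) -> np.ndarray:
    x = np.asarray(values, dtype=float)
    k = x.shape[1]
    cols = [x]
    for i in range(k):
        for j in range(i + 1, k):
            cols.append((x[:, i] * x[:, j])[:, None])
    return np.hstack(cols)


def fit_logistic_pairwise(
    values, labels, eval_values=None, ridge_on_failure: float = 1e-6
):
    """Logistic regression with main effects and all pairwise products.

    Genotypes are coded 0/1/2 (levels for environmental columns); the design
    holds every column ``s_i`` and every product ``s_i * s_j`` (i < j).
    Degenerate (constant) design columns are dropped with a warning.  The
    model is fit by maximum likelihood; on separation or non-convergence a
    small ridge penalty is applied and a warning issued.

    Returns fitted case probabilities for the training individuals, or for
    ``eval_values`` when given (out-of-sample scoring).
    """
    import statsmodels.api as sm

    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 markers for the pairwise model")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    design = _pairwise_design(x)
    keep = design.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} degenerate (constant) design column(s)",
            stacklevel=2,
        )
    design = design[:, keep]
    design = sm.add_constant(design, has_constant="add")
    if eval_values is None:
        target = design
    else:
        target = _pairwise_design(np.asarray(eval_values, dtype=float))[:, keep]
        target = sm.add_constant(target, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0, maxiter=200, tol=1e-8)
        if not np.all(np.isfinite(res.params)) or not res.mle_retvals.get(
            "converged", False
        ):
            raise RuntimeError("MLE did not converge")
        return np.asarray(res.predict(target))
    except Exception:
        warnings.warn(
            "logistic MLE failed (separation or non-convergence); "
            f"refitting with ridge penalty {ridge_on_failure}",
            stacklevel=2,
        )
        from sklearn.linear_model import LogisticRegression

        n = len(y)
        clf = LogisticRegression(
            penalty="l2",
            C=1.0 / (ridge_on_failure * n),
            solver="lbfgs",
            max_iter=2000,
            tol=1e-8,
            fit_intercept=False,  # constant column already in the design
        )
        clf.fit(design, y)
        return clf.predict_proba(target)[:, 1]


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------


def experiment_optimal_auc(
    disease: DiseaseParams, n: int = 100_000, seed: int | np.random.Generator = 0
) -> float:
    """Theoretical genetic maximum AUC by simulation (latent G as the score)."""
    spec = calibrate_model1(disease)
    g, _e, status = sample_model1(spec, n, seed)
    return _rank_auc(g, status)


_FIXTURE_KEYS = {
    "t2d": ("t2d_table1", "t2d_env"),
    "crohns": ("crohns_table1", "crohns_env"),
    "ra": ("ra_table1", "ra_env"),
}


def experiment_gci_vs_egci(
    disease_key: str,
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Simulate an EGCI-driven cohort; AUC of genetics-only GCI vs full EGCI.

    ``disease_key`` is one of ``t2d``, ``crohns``, ``ra``.  Genotypes and
    environmental levels are drawn from the bundled published tables, status
    is Bernoulli with probability equal to the EGCI score, and both scores
    are evaluated on the same cohort.
    """
    if disease_key not in _FIXTURE_KEYS:
        raise ValueError(f"unknown disease key {disease_key!r}")
    gen_name, env_name = _FIXTURE_KEYS[disease_key]
    fixtures = load_fixtures()
    gen_markers, disease = fixtures[gen_name]
    env_markers, _ = fixtures[env_name]
    markers = tuple(gen_markers) + tuple(env_markers)
    rng = np.random.default_rng(seed)
    gm = simulate_genotypes(markers, n, rng)
    cohort = Cohort(genotypes=gm, markers=markers)
    assign_status_multiplicative(cohort, disease, rng)
    genetic_cols = cohort.genetic_columns()
    gci = cohort_scores(gm.values, markers, disease, columns=genetic_cols)
    egci = cohort_scores(gm.values, markers, disease)
    status = cohort.status
    return _rank_auc(gci, status), _rank_auc(egci, status)


def experiment_interaction_vs_multiplicative(
    disease_key: str,
    gamma: float,
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
    pair: tuple[str, str] | None = None,
) -> tuple[float, float]:
    """AUC of the true interaction risk vs the multiplicative GCI score.

    One SNP pair (by default the two markers with the largest heterozygote
    relative risks) interacts with boost factor ``gamma``; marginal relative
    risks are re-matched to the published values.  Status is drawn from the
    interaction model; both scores are evaluated on the same cohort.
    """
    gen_name, _ = _FIXTURE_KEYS[disease_key]
    fixtures = load_fixtures()
    markers, disease = fixtures[gen_name]
    markers = tuple(markers)
    if pair is None:
        order = sorted(markers, key=lambda m: m.rel_risks[1], reverse=True)
        pair = (order[0].id, order[1].id)
    by_id = {m.id: m for m in markers}
    spec = solve_interaction_lambdas(by_id[pair[0]], by_id[pair[1]], gamma, disease)
    rng = np.random.default_rng(seed)
    gm = simulate_genotypes(markers, n, rng)
    cohort = Cohort(genotypes=gm, markers=markers)
    assign_status_interaction(cohort, spec, disease, rng)
    true_score = interaction_relative_risks(cohort, spec)
    mult_score = cohort_scores(gm.values, markers, disease)
    return _rank_auc(true_score, cohort.status), _rank_auc(mult_score, cohort.status)


@dataclass
class RelativeErrorResult:
    """Paired absolute relative errors of lifetime-risk estimates."""

    err_rr_based: np.ndarray
    err_or_based: np.ndarray
    est_rr_based: np.ndarray
    est_or_based_uncapped: np.ndarray
    true_risks: np.ndarray
    alpha: float


def _gci_from_genotype_rrs(
    x: np.ndarray, rr_table: np.ndarray, geno_freqs: np.ndarray, altr: float
) -> np.ndarray:
    """Uncapped multiplicative lifetime-risk estimates from per-genotype RRs."""
    log_rr = np.zeros(x.shape[0])
    log_norm = 0.0
    for j in range(x.shape[1]):
        log_rr += np.log(rr_table[j])[x[:, j]]
        log_norm += np.log(geno_freqs[j] @ rr_table[j])
    return altr * np.exp(log_rr - log_norm)


def experiment_relative_error(
    disease: DiseaseParams,
    het_rrs,
    allele_freqs,
    n_cases: int = 10_000,
    n_eval: int = 500,
    seed: int | np.random.Generator = 0,
    onset_mean: float = 50.0,
    onset_sd: float = 13.0,
    force_alpha: float | None = None,
    model2: LiabilityModel2Spec | None = None,
) -> RelativeErrorResult:
    """Absolute relative error of lifetime-risk estimates from a simulated study.

    An age-matched case-control study is simulated under liability model 2,
    per-SNP odds ratios are estimated from it, and two sets of per-genotype
    relative risks are built: (a) odds ratios converted via the
    diseased-control correction (``alpha`` from the control ages unless
    ``force_alpha`` is given), and (b) the raw odds ratios used as if they
    were relative risks.  Both are applied as multiplicative lifetime-risk
    estimates to ``n_eval`` fresh individuals and compared against each
    individual's correct genetic risk: the exact lifetime disease
    probability given their genotypes at the modelled SNPs, integrating over
    the unobserved polygenic and environmental liability.
    """
    rng = np.random.default_rng(seed)
    if model2 is None:
        model2 = solve_lambdas_model2(het_rrs, allele_freqs, disease)
    study = simulate_age_structured_casecontrol(
        model2, n_cases, onset_mean=onset_mean, onset_sd=onset_sd, seed=rng
    )
    alpha = (
        force_alpha
        if force_alpha is not None
        else alpha_from_ages(study.control_ages, onset_mean, onset_sd, disease.altr)
    )
    p = np.asarray(model2.allele_freqs)
    geno_freqs = np.column_stack(((1 - p) ** 2, 2 * p * (1 - p), p**2))
    k = len(p)
    rr_conv = np.ones((k, 3))
    rr_raw = np.ones((k, 3))
    for j in range(k):
        ors = study.odds_ratios[j]
        sol = solve_penetrances(
            ConversionProblem(
                (1.0, float(ors[1]), float(ors[2])),
                tuple(geno_freqs[j]),
                disease.altr,
                alpha,
            )
        )
        rr_conv[j] = sol.rel_risks
        rr_raw[j] = ors

    # fresh evaluation cohort with known true risks
    x, _g, _e, _status = sample_model2(model2, n_eval, rng)
    from scipy.special import ndtr

    s_rest = float(np.hypot(model2.sigma_g1, model2.sigma_e))
    true_risk = ndtr((x @ np.asarray(model2.lambdas) - model2.threshold) / s_rest)
    est_rr = _gci_from_genotype_rrs(x, rr_conv, geno_freqs, disease.altr)
    est_or = _gci_from_genotype_rrs(x, rr_raw, geno_freqs, disease.altr)
    err_rr = np.abs(np.minimum(est_rr, 1.0) - true_risk) / true_risk
    err_or = np.abs(np.minimum(est_or, 1.0) - true_risk) / true_risk
    return RelativeErrorResult(
        err_rr_based=err_rr,
        err_or_based=err_or,
        est_rr_based=est_rr,
        est_or_based_uncapped=est_or,
        true_risks=true_risk,
        alpha=float(alpha),
    )
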