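"""Cohort simulators for evaluating composite-index risk scores.

Three generative designs are provided:

* **Multiplicative cohorts** — genotypes and environmental levels are drawn
  independently from their population frequencies and disease status is
  Bernoulli with probability equal to the individual's (E)GCI score, so the
  multiplicative independent-loci model is true by construction and the case
  fraction converges to the average lifetime risk.
* **Pairwise-interaction cohorts** — one SNP pair deviates from
  multiplicativity: the joint relative risk of selected genotype
  combinations is ``gamma`` times the product of the pair's per-genotype
  effects.  The pair's per-genotype effects are re-solved so that each SNP's
  *marginal* relative risks still match the published univariate values,
  i.e. a study examining one SNP at a time would see exactly the summary
  statistics it reports, while the joint model is epistatic.
* **Age-structured case-control studies** — individuals from liability
  model 2 receive an age (uniform on [0, 100]) and, if destined to develop
  the disease, an age of onset (normal, truncated to [0, 100]); a sampled
  individual is an *observed* case only when past onset.  Each observed case
  is matched to one control on integer age.  Controls therefore include
  pre-onset lifetime cases — the contamination that distinguishes lifetime
  relative risks from case-control odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

from .core_io import DiseaseParams, GenotypeMatrix, Marker
from .liability import LiabilityModel2Spec
from .riskmodel import cohort_scores, mean_relative_risk

__all__ = [
    "Cohort",
    "InteractionSpec",
    "CaseControlStudy",
    "DEFAULT_BOOSTED_COMBOS",
    "simulate_genotypes",
    "assign_status_multiplicative",
    "solve_interaction_lambdas",
    "interaction_relative_risks",
    "assign_status_interaction",
    "simulate_age_structured_casecontrol",
]

#: default set of boosted genotype pairs: both SNPs carry at least one risk
#: allele (symmetric, nonempty, leaves the marginal system solvable).
DEFAULT_BOOSTED_COMBOS: frozenset[tuple[int, int]] = frozenset(
    {(1, 1), (1, 2), (2, 1), (2, 2)}
)


@dataclass
class Cohort:
    """Simulated individuals: genotypes/levels, optional latents and status."""

    genotypes: GenotypeMatrix
    markers: tuple[Marker, ...]
    status: np.ndarray | None = None
    age: np.ndarray | None = None
    onset_age: np.ndarray | None = None
    latent_g: np.ndarray | None = None
    latent_e: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    def genetic_columns(self) -> list[int]:
        return [j for j, m in enumerate(self.markers) if m.kind == "genetic"]


@dataclass(frozen=True)
class InteractionSpec:
    """A solved pairwise SNP-SNP interaction.

    ``lambdas_x``/``lambdas_y`` are the per-genotype relative-risk factors of
    the interacting pair (baseline 1); the joint relative risk of a boosted
    combination ``(g_x, g_y)`` is ``gamma * lambdas_x[g_x] * lambdas_y[g_y]``.
    """

    pair: tuple[str, str]
    gamma: float
    boosted_combos: frozenset[tuple[int, int]]
    lambdas_x: tuple[float, float, float]
    lambdas_y: tuple[float, float, float]


@dataclass
class CaseControlStudy:
    """An age-matched case-control study with per-SNP odds-ratio estimates."""

    case_values: np.ndarray
    control_values: np.ndarray
    case_ages: np.ndarray
    control_ages: np.ndarray
    control_lifetime_status: np.ndarray
    odds_ratios: np.ndarray  # shape (k, 3); column 0 is 1.0
    seed: int | None = None


def simulate_genotypes(
    markers: Sequence[Marker], n: int, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Draw independent level indices from each marker's level frequencies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = []
    for m in markers:
        freqs = np.asarray(m.freqs, dtype=float)
        cum = np.cumsum(freqs / freqs.sum())
        u = rng.random(n)
        cols.append(np.searchsorted(cum, u, side="right").clip(0, m.n_levels - 1))
    values = np.column_stack(cols).astype(np.int64)
    ids = [f"ind{i}" for i in range(n)]
    return GenotypeMatrix(ids, [m.id for m in markers], values)


def assign_status_multiplicative(
    cohort: Cohort,
    disease: DiseaseParams,
    seed: int | np.random.Generator,
) -> Cohort:
    """Bernoulli disease status with probability equal to the (E)GCI score."""
    rng = np.random.default_rng(seed)
    p = cohort_scores(cohort.genotypes.values, cohort.markers, disease)
    cohort.status = (rng.random(cohort.n) < p).astype(np.int8)
    cohort.meta["seed"] = seed if isinstance(seed, int) else None
    cohort.meta["model"] = "multiplicative"
    return cohort


# ---------------------------------------------------------------------------
# Pairwise interaction model
# ---------------------------------------------------------------------------


def _pair_weight(
    lx: np.ndarray, ly: np.ndarray, gamma: float, boosted, gx: int, gy: int
) -> float:
    w = lx[gx] * ly[gy]
    return w * gamma if (gx, gy) in boosted else w


def _marginal_rel_risks(
    lx: np.ndarray,
    ly: np.ndarray,
    fx: np.ndarray,
    fy: np.ndarray,
    gamma: float,
    boosted,
) -> tuple[np.ndarray, np.ndarray]:
    """Frequency-weighted marginal relative risks of each SNP in the pair."""
    w = np.array(
        [
            [_pair_weight(lx, ly, gamma, boosted, gx, gy) for gy in range(3)]
            for gx in range(3)
        ]
    )
    mx = w @ fy  # E over gy for each gx
    my = fx @ w
    return mx / mx[0], my / my[0]


def solve_interaction_lambdas(
    marker_x: Marker,
    marker_y: Marker,
    gamma: float,
    disease: DiseaseParams,
    boosted_combos=DEFAULT_BOOSTED_COMBOS,
) -> InteractionSpec:
    """Solve pair effects so marginal relative risks match the published ones.

    Four unknowns (heterozygote and homozygote factors of each SNP in the
    pair) are solved in log space with a damped root-finder so that the
    frequency-weighted marginal relative risks of each SNP under the
    gamma-boosted joint model equal the markers' printed values.  With
    ``gamma = 1`` the solution is the printed values themselves.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not boosted_combos:
        raise ValueError("boosted_combos must be nonempty")
    boosted = frozenset(boosted_combos)
    fx = np.asarray(marker_x.freqs)
    fy = np.asarray(marker_y.freqs)
    tx = np.asarray(marker_x.rel_risks)
    ty = np.asarray(marker_y.rel_risks)

    def residuals(log_l: np.ndarray) -> np.ndarray:
        lx = np.array([1.0, np.exp(log_l[0]), np.exp(log_l[1])])
        ly = np.array([1.0, np.exp(log_l[2]), np.exp(log_l[3])])
        rx, ry = _marginal_rel_risks(lx, ly, fx, fy, gamma, boosted)
        return np.array(
            [rx[1] - tx[1], rx[2] - tx[2], ry[1] - ty[1], ry[2] - ty[2]]
        )

    x0 = np.log([tx[1], tx[2], ty[1], ty[2]])
    sol = optimize.root(residuals, x0, method="hybr", tol=1e-12)
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise RuntimeError(
            f"interaction marginal-matching solver failed for pair "
            f"({marker_x.id}, {marker_y.id}), gamma={gamma}: {sol.message}"
        )
    lx = (1.0, float(np.exp(sol.x[0])), float(np.exp(sol.x[1])))
    ly = (1.0, float(np.exp(sol.x[2])), float(np.exp(sol.x[3])))
    return InteractionSpec(
        pair=(marker_x.id, marker_y.id),
        gamma=float(gamma),
        boosted_combos=boosted,
        lambdas_x=lx,
        lambdas_y=ly,
    )


def interaction_relative_risks(
    cohort: Cohort, spec: InteractionSpec
) -> np.ndarray:
    """Per-individual relative risk under the true interaction model."""
    marker_ids = list(cohort.genotypes.marker_ids)
    jx = marker_ids.index(spec.pair[0])
    jy = marker_ids.index(spec.pair[1])
    values = cohort.genotypes.values
    log_rr = np.zeros(cohort.n)
    for j, m in enumerate(cohort.markers):
        if j in (jx, jy):
            continue
        log_rr += np.log(np.asarray(m.rel_risks))[values[:, j]]
    lx = np.asarray(spec.lambdas_x)
    ly = np.asarray(spec.lambdas_y)
    gx, gy = values[:, jx], values[:, jy]
    pair_rr = lx[gx] * ly[gy]
    boost = np.array(
        [[(a, b) in spec.boosted_combos for b in range(3)] for a in range(3)]
    )
    pair_rr = np.where(boost[gx, gy], pair_rr * spec.gamma, pair_rr)
    return np.exp(log_rr) * pair_rr


def _interaction_mean_rr(cohort_markers, spec: InteractionSpec) -> float:
    """Exact population mean of the interaction-model relative risk."""
    mean = 1.0
    mx = my = None
    for m in cohort_markers:
        if m.id == spec.pair[0]:
            mx = m
        elif m.id == spec.pair[1]:
            my = m
        else:
            mean *= mean_relative_risk(m)
    fx = np.asarray(mx.freqs)
    fy = np.asarray(my.freqs)
    lx = np.asarray(spec.lambdas_x)
    ly = np.asarray(spec.lambdas_y)
    pair_mean = 0.0
    for gx in range(3):
        for gy in range(3):
            pair_mean += fx[gx] * fy[gy] * _pair_weight(
                lx, ly, spec.gamma, spec.boosted_combos, gx, gy
            )
    return mean * pair_mean


def assign_status_interaction(
    cohort: Cohort,
    spec: InteractionSpec,
    disease: DiseaseParams,
    seed: int | np.random.Generator,
) -> Cohort:
    """Bernoulli status with probability ``lambda_i / C`` under the pair model.

    The normalizing constant ``C = E[lambda] / ALTR`` uses the exact
    population expectation of the interaction relative risk, so the expected
    case fraction equals the average lifetime risk and ``gamma = 1``
    reproduces :func:`assign_status_multiplicative` draw for draw.
    """
    rng = np.random.default_rng(seed)
    lam = interaction_relative_risks(cohort, spec)
    c = _interaction_mean_rr(cohort.markers, spec) / disease.altr
    p = np.minimum(lam / c, 1.0)
    cohort.status = (rng.random(cohort.n) < p).astype(np.int8)
    cohort.meta["seed"] = seed if isinstance(seed, int) else None
    cohort.meta["model"] = f"interaction(gamma={spec.gamma})"
    return cohort


# ---------------------------------------------------------------------------
# Age-structured case-control design
# ---------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int, lo=0.0, hi=100.0
) -> np.ndarray:
    """Normal variates truncated to [lo, hi] by resampling."""
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def simulate_age_structured_casecontrol(
    model2: LiabilityModel2Spec,
    n_cases: int,
    onset_mean: float = 50.0,
    onset_sd: float = 13.0,
    seed: int | np.random.Generator = 0,
    age_range: tuple[float, float] = (0.0, 100.0),
    max_batches: int = 200,
) -> CaseControlStudy:
    """Simulate an age-matched case-control study under liability model 2.

    Individuals are drawn with age ~ Uniform[0, 100]; lifetime-diseased
    individuals (liability above threshold) get an onset age ~
    Normal(onset_mean, onset_sd) truncated to [0, 100] and are *observed*
    cases only if already past onset.  Each observed case is matched with one
    not-yet-observed-case control of the same integer age; a control is used
    at most once.  Per-SNP odds ratios are estimated from the resulting
    2x3 genotype tables (0.5 continuity correction when a cell is empty).
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.asarray(model2.allele_freqs)
    k = len(p)

    case_vals: list[np.ndarray] = []
    case_ages: list[float] = []
    # age-bucketed pools of available controls: (genotypes, true age, lifetime status)
    ctrl_pool: dict[int, list[tuple[np.ndarray, float, int]]] = {
        a: [] for a in range(101)
    }
    need_ages: dict[int, int] = {}

    matched_vals: list[np.ndarray] = []
    matched_ages: list[float] = []
    matched_life: list[int] = []

    batch = max(4 * n_cases, 10_000)
    for _ in range(max_batches):
        if len(case_vals) >= n_cases and not need_ages:
            break
        x = rng.binomial(2, p, size=(batch, k))
        g = x @ np.asarray(model2.lambdas) + (
            rng.normal(0.0, model2.sigma_g1, batch) if model2.sigma_g1 > 0 else 0.0
        )
        e = rng.normal(0.0, model2.sigma_e, batch) if model2.sigma_e > 0 else 0.0
        lifetime = (g + e > model2.threshold).astype(np.int8)
        age = rng.uniform(age_range[0], age_range[1], batch)
        onset = np.full(batch, np.inf)
        n_dis = int(lifetime.sum())
        if n_dis:
            onset[lifetime == 1] = _truncated_normal(rng, onset_mean, onset_sd, n_dis)
        observed_case = (lifetime == 1) & (age >= onset)

        for i in range(batch):
            a = min(int(age[i]), 100)
            if observed_case[i]:
                if len(case_vals) < n_cases:
                    case_vals.append(x[i])
                    case_ages.append(float(age[i]))
                    # try to match immediately from the pool
                    if ctrl_pool[a]:
                        cv, ca, cl = ctrl_pool[a].pop()
                        matched_vals.append(cv)
                        matched_ages.append(ca)
                        matched_life.append(cl)
                    else:
                        need_ages[a] = need_ages.get(a, 0) + 1
            else:
                if need_ages.get(a, 0) > 0:
                    matched_vals.append(x[i])
                    matched_ages.append(float(age[i]))
                    matched_life.append(int(lifetime[i]))
                    need_ages[a] -= 1
                    if need_ages[a] == 0:
                        del need_ages[a]
                elif len(ctrl_pool[a]) < 50:
                    ctrl_pool[a].append((x[i], float(age[i]), int(lifetime[i])))
    if len(case_vals) < n_cases or need_ages:
        raise RuntimeError(
            "age matching exhausted the resampling budget "
            f"({len(case_vals)}/{n_cases} cases, unmatched ages {need_ages})"
        )

    case_arr = np.asarray(case_vals)
    ctrl_arr = np.asarray(matched_vals)
    ors = np.ones((k, 3))
    for j in range(k):
        a_counts = np.bincount(case_arr[:, j], minlength=3).astype(float)
        b_counts = np.bincount(ctrl_arr[:, j], minlength=3).astype(float)
        if np.any(a_counts == 0) or np.any(b_counts == 0):
            a_counts += 0.5
            b_counts += 0.5
        ors[j, 1] = (a_counts[1] / a_counts[0]) / (b_counts[1] / b_counts[0])
        ors[j, 2] = (a_counts[2] / a_counts[0]) / (b_counts[2] / b_counts[0])
    return CaseControlStudy(
        case_values=case_arr,
        control_values=ctrl_arr,
        case_ages=np.asarray(case_ages),
        control_ages=np.asarray(matched_ages),
        control_lifetime_status=np.asarray(matched_life, dtype=np.int8),
        odds_ratios=ors,
        seed=seed if isinstance(seed, int) else None,
    )
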