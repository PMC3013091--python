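"""Odds-ratio to relative-risk conversion with diseased controls.

Case-control studies report odds ratios, not lifetime relative risks.  On the
lifetime-risk scale a fraction ``alpha`` of the study's controls will
eventually develop the disease, which attenuates the odds ratios relative to
what population controls would show.  Writing ``x_i = Pr(D | a_i)`` for the
lifetime penetrance of level ``a_i`` (``a_0`` is the baseline), the level
distribution among controls is the mixture

    Pr(a_i | control) = alpha * Pr(a_i | D) + (1 - alpha) * Pr(a_i | not D)

and the observed odds ratio of level i versus baseline is

    OR_i = (x_i / x_0) * c(x_0) / c(x_i),
    c(x)  = alpha * x / Pr(D) + (1 - alpha) * (1 - x) / (1 - Pr(D)).

Given the odds ratios, the level frequencies f_i and the average lifetime
risk Pr(D), the penetrances are pinned down by the population constraint
``sum_i f_i x_i = Pr(D)``.  For a fixed candidate ``x_0`` each ``x_i``
follows in closed form (the identity is linear in ``x_i``), and the
constraint function is strictly increasing in ``x_0``, so a bisection on
``x_0 in (0, Pr(D))`` finds the unique solution.

Special cases worth noting: with ``alpha = Pr(D)`` (controls are a random
population sample) the odds ratios equal the lifetime relative risks exactly;
with ``alpha = 0`` the conversion reduces to the classical prevalence-based
one; and as ``Pr(D) -> 0`` odds ratios converge to relative risks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ConversionProblem",
    "PenetranceSolution",
    "solve_penetrances",
    "odds_ratios_from_penetrances",
    "estimate_alpha_mle",
    "alpha_from_ages",
]

_BISECT_TOL = 1e-12
_BISECT_MAX_ITER = 200


@dataclass(frozen=True)
class ConversionProblem:
    """Odds ratios, level frequencies and disease parameters for one locus.

    A "locus" may represent several interacting SNPs jointly (``3**s`` levels
    for ``s`` SNPs); the baseline level comes first and has ``OR = 1``.
    """

    odds_ratios: tuple[float, ...]
    freqs: tuple[float, ...]
    altr: float
    alpha_controls: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.odds_ratios[0] - 1.0) > 1e-12:
            raise ValueError("baseline odds ratio must be 1.0")
        if any(o <= 0 for o in self.odds_ratios):
            raise ValueError("odds ratios must be positive")
        if len(self.freqs) != len(self.odds_ratios):
            raise ValueError("freqs and odds_ratios length mismatch")
        if any(f < 0 for f in self.freqs) or abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("frequencies must be nonnegative and sum to 1")
        if not 0.0 < self.altr < 1.0:
            raise ValueError("average lifetime risk must be in (0,1)")
        if not 0.0 <= self.alpha_controls <= self.altr + 1e-12:
            raise ValueError("alpha_controls must lie in [0, altr]")


@dataclass(frozen=True)
class PenetranceSolution:
    """Per-level lifetime penetrances and the implied relative risks."""

    p_d_given_level: tuple[float, ...]
    rel_risks: tuple[float, ...]


def _mixture_coeffs(altr: float, alpha: float) -> tuple[float, float]:
    """Coefficients (A, B) of the control mixture c(x) = B + (A - B) x."""
    return alpha / altr, (1.0 - alpha) / (1.0 - altr)


def _penetrances_given_x0(
    x0: float, odds_ratios: np.ndarray, altr: float, alpha: float
) -> np.ndarray:
    """All level penetrances for a candidate baseline penetrance ``x0``.

    Solves ``OR_i x0 c(x_i) = x_i c(x0)`` for each ``x_i`` (linear in x_i).
    Candidates for which the implied x_i would leave (0, 1) are clamped to 1,
    which keeps the population-constraint function monotone.
    """
    a, b = _mixture_coeffs(altr, alpha)
    c0 = b + (a - b) * x0
    denom = c0 - odds_ratios * x0 * (a - b)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = odds_ratios * x0 * b / denom
    x = np.where((denom <= 0) | (x > 1.0), 1.0, x)
    x[0] = x0
    return x


def solve_penetrances(problem: ConversionProblem) -> PenetranceSolution:
    """Solve for per-level lifetime penetrances given odds ratios.

    Bisection on the baseline penetrance ``Pr(D | a_0)``; the
    frequency-weighted mean of the solution equals the average lifetime risk
    to within the bisection tolerance.  When every odds ratio is >= 1 (the
    baseline is the lowest-risk level) the unique solution lies in
    ``(0, Pr(D))``; odds ratios below 1 (e.g. noisy estimates) can push the
    baseline penetrance above ``Pr(D)``, so the search runs over ``(0, 1)``.
    """
    ors = np.asarray(problem.odds_ratios, dtype=float)
    freqs = np.asarray(problem.freqs, dtype=float)
    altr, alpha = problem.altr, problem.alpha_controls

    def constraint(x0: float) -> float:
        return float(freqs @ _penetrances_given_x0(x0, ors, altr, alpha)) - altr

    lo, hi = 0.0, (altr if np.all(ors >= 1.0) else 1.0 - 1e-12)
    f_hi = constraint(hi)
    if f_hi < -1e-9:
        raise ValueError(
            "no penetrance solution: the frequency-weighted mean penetrance "
            "stays below the average lifetime risk even at the "
            "baseline-penetrance upper bound (odds ratios/frequencies/altr "
            "inconsistent)"
        )
    for _ in range(_BISECT_MAX_ITER):
        mid = 0.5 * (lo + hi)
        if constraint(mid) < 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < _BISECT_TOL:
            break
    x0 = 0.5 * (lo + hi)
    x = _penetrances_given_x0(x0, ors, altr, alpha)
    if np.any(x >= 1.0) or np.any(x <= 0.0):
        raise ValueError(
            "penetrance solution leaves (0,1); odds ratios are inconsistent "
            "with the stated frequencies and average lifetime risk"
        )
    return PenetranceSolution(
        p_d_given_level=tuple(float(v) for v in x),
        rel_risks=tuple(float(v / x[0]) for v in x),
    )


def odds_ratios_from_penetrances(
    solution: PenetranceSolution,
    freqs: Sequence[float],
    altr: float,
    alpha_controls: float,
) -> tuple[float, ...]:
    """Forward map from lifetime penetrances to study odds ratios.

    Exact inverse of :func:`solve_penetrances` for the same ``(freqs, altr,
    alpha_controls)``.  ``freqs`` only enters through the problem definition
    (the forward map itself is frequency-free) and is accepted for symmetry.
    """
    x = np.asarray(solution.p_d_given_level, dtype=float)
    a, b = _mixture_coeffs(altr, alpha_controls)
    c = b + (a - b) * x
    ors = (x / x[0]) * (c[0] / c)
    return tuple(float(v) for v in ors)


def estimate_alpha_mle(
    case_counts: Sequence[float],
    control_counts: Sequence[float],
    freqs: Sequence[float],
    altr: float,
    n_grid: int = 21,
) -> tuple[float, dict]:
    """Maximum-likelihood estimate of the diseased-control fraction ``alpha``.

    For each candidate alpha, the observed odds ratios are converted to
    penetrances (:func:`solve_penetrances`) and the multinomial likelihood of
    the observed case and control level counts is evaluated under the implied
    case distribution ``f_i x_i / Pr(D)`` and control mixture distribution.
    A grid pre-scan over ``[0, altr]`` seeds a golden-section refinement.

    Returns ``(alpha_hat, info)`` where ``info`` holds the profile
    (``alphas``, ``loglik``) and a ``degenerate`` flag set when the
    likelihood is flat (no association at any level).
    """
    n1 = np.asarray(case_counts, dtype=float)
    n0 = np.asarray(control_counts, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if np.any(n1 < 0) or np.any(n0 < 0) or n1.sum() <= 0 or n0.sum() <= 0:
        raise ValueError("need nonnegative counts with at least one case and control")
    if n1[0] <= 0 or n0[0] <= 0:
        raise ValueError("baseline level must be observed in both arms")
    ors = (n1 / n1[0]) / (n0 / n0[0])
    ors[0] = 1.0

    def loglik(alpha: float) -> float:
        try:
            sol = solve_penetrances(
                ConversionProblem(tuple(ors), tuple(f), altr, min(alpha, altr))
            )
        except ValueError:
            # observed ORs inconsistent with altr at this candidate alpha
            return -np.inf
        x = np.asarray(sol.p_d_given_level)
        q1 = f * x / (f @ x)
        a, b = _mixture_coeffs(altr, min(alpha, altr))
        c = b + (a - b) * x
        q0 = f * c / (f @ c)
        with np.errstate(divide="ignore"):
            return float(n1 @ np.log(q1) + n0 @ np.log(q0))

    grid = np.linspace(0.0, altr, n_grid)
    lls = np.array([loglik(a) for a in grid])
    degenerate = bool(lls.max() - lls.min() < 1e-8)
    if degenerate:
        return 0.0, {"alphas": grid, "loglik": lls, "degenerate": True}

    k = int(np.argmax(lls))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    # golden-section maximization on [lo, hi]
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a_, b_ = lo, hi
    c_ = b_ - invphi * (b_ - a_)
    d_ = a_ + invphi * (b_ - a_)
    fc, fd = loglik(c_), loglik(d_)
    for _ in range(60):
        if b_ - a_ < 1e-10:
            break
        if fc > fd:
            b_, d_, fd = d_, c_, fc
            c_ = b_ - invphi * (b_ - a_)
            fc = loglik(c_)
        else:
            a_, c_, fc = c_, d_, fd
            d_ = a_ + invphi * (b_ - a_)
            fd = loglik(d_)
    alpha_hat = float(np.clip(0.5 * (a_ + b_), 0.0, altr))
    return alpha_hat, {"alphas": grid, "loglik": lls, "degenerate": False}


def alpha_from_ages(
    control_ages: Sequence[float],
    onset_mean: float,
    onset_sd: float,
    altr: float,
) -> float:
    """Diseased-control fraction implied by the study's control ages.

    A control of age ``a`` who is destined to develop the disease has not yet
    done so with probability ``Pr(onset > a)`` under the Normal(onset_mean,
    onset_sd) age-of-onset model, hence

        alpha = altr * mean_controls Pr(onset > age).
    """
    ages = np.asarray(control_ages, dtype=float)
    if ages.size == 0:
        raise ValueError("empty control age list")
    if onset_sd <= 0:
        raise ValueError("onset_sd must be positive")
    if np.any(ages < 0):
        raise ValueError("ages must be nonnegative")
    return float(altr * np.mean(stats.norm.sf(ages, loc=onset_mean, scale=onset_sd)))
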