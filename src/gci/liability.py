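"""Liability-threshold disease models and theoretical-maximum AUC.

Model 1: the latent phenotype is ``P = G + E`` with independent normals
``G ~ N(0, sigma_g^2)`` and ``E ~ N(0, sigma_e^2)``; an individual develops
the disease in their lifetime iff ``P > threshold``.  On the canonical
unit-total-variance scale, ``sigma_g^2`` equals the heritability ``h`` and
the threshold is the standard-normal quantile at ``1 - ALTR``.  The AUC of a
classifier that knows G exactly (the *theoretical genetic maximum*) depends
only on ``(h, ALTR)`` — rescaling all three parameters by a common factor
leaves the ROC curve unchanged.

Model 2 splits the genetic liability into a few large-effect SNPs and a
polygenic remainder: ``G = sum_i lambda_i X_i + G1`` with ``X_i ~
Binomial(2, p_i)`` and ``G1 ~ N(0, sigma_g1^2)``, under the variance budget
``sigma_g1^2 + sum_i 2 p_i (1-p_i) lambda_i^2 = h``.  The per-SNP liability
effects are solved so that the model-implied heterozygote relative risks
match given targets; the distribution of the other-SNP liability sum is
computed exactly by dynamic-programming convolution on a value grid, and the
per-genotype disease probabilities use the normal survival function
(complementary error function).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .core_io import DiseaseParams

__all__ = [
    "LiabilityModel1Spec",
    "LiabilityModel2Spec",
    "calibrate_model1",
    "sample_model1",
    "true_risk_given_g",
    "theoretical_max_auc",
    "model1_auc_analytic",
    "solve_lambdas_model2",
    "sample_model2",
    "implied_het_rel_risks",
    "variance_explained_from_auc",
    "variance_explained_from_lambdas",
]

#: value-grid resolution (in units of total liability SD) for the exact
#: convolution of the large-effect liability sum; colliding atoms merge.
#: Summing over all 3**k genotype configurations verbatim is infeasible for
#: panels of ~27 SNPs; the gridded convolution is exact up to this rounding.
_GRID_RES = 1e-4


@dataclass(frozen=True)
class LiabilityModel1Spec:
    """Calibrated two-normal liability model."""

    sigma_g: float
    sigma_e: float
    threshold: float
    disease: DiseaseParams

    @property
    def total_sd(self) -> float:
        return float(np.hypot(self.sigma_g, self.sigma_e))

    def rescaled(self, factor: float) -> "LiabilityModel1Spec":
        """Multiply all scale parameters by ``factor`` (same disease)."""
        return LiabilityModel1Spec(
            self.sigma_g * factor,
            self.sigma_e * factor,
            self.threshold * factor,
            self.disease,
        )


@dataclass(frozen=True)
class LiabilityModel2Spec:
    """Liability model with explicit large-effect SNPs plus polygenic rest."""

    lambdas: tuple[float, ...]
    allele_freqs: tuple[float, ...]
    sigma_g1: float
    sigma_e: float
    threshold: float
    disease: DiseaseParams

    def rescaled(self, factor: float) -> "LiabilityModel2Spec":
        return LiabilityModel2Spec(
            tuple(l * factor for l in self.lambdas),
            self.allele_freqs,
            self.sigma_g1 * factor,
            self.sigma_e * factor,
            self.threshold * factor,
            self.disease,
        )


# ---------------------------------------------------------------------------
# Model 1
# ---------------------------------------------------------------------------


def calibrate_model1(disease: DiseaseParams) -> LiabilityModel1Spec:
    """Calibrate model 1 on the unit-total-variance scale.

    ``sigma_g = sqrt(h)``, ``sigma_e = sqrt(1-h)`` and the threshold is the
    standard-normal quantile at ``1 - ALTR``, so that
    ``Pr(G + E > threshold) = ALTR`` exactly.
    """
    h = disease.heritability
    return LiabilityModel1Spec(
        sigma_g=float(np.sqrt(h)),
        sigma_e=float(np.sqrt(1.0 - h)),
        threshold=float(ndtri(1.0 - disease.altr)),
        disease=disease,
    )


def sample_model1(
    spec: LiabilityModel1Spec, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``(G, E, status)`` for ``n`` individuals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    g = rng.normal(0.0, spec.sigma_g, n) if spec.sigma_g > 0 else np.zeros(n)
    e = rng.normal(0.0, spec.sigma_e, n) if spec.sigma_e > 0 else np.zeros(n)
    status = (g + e > spec.threshold).astype(np.int8)
    return g, e, status


def true_risk_given_g(spec: LiabilityModel1Spec, g: float | np.ndarray) -> np.ndarray:
    """Lifetime disease probability given the exact genetic liability.

    ``Pr(D | G = g) = 1 - Phi((threshold - g) / sigma_e)``.
    """
    if spec.sigma_e <= 0:
        raise ValueError("true_risk_given_g requires sigma_e > 0")
    return ndtr((np.asarray(g, dtype=float) - spec.threshold) / spec.sigma_e)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney AUC."""
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError(
            "need both cases and controls to compute an AUC "
            "(increase n for small lifetime risks)"
        )
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def model1_auc_analytic(
    var_known: float, altr: float, n_grid: int = 40001
) -> float:
    """AUC of a normal liability component of variance ``var_known``.

    The classifier is ``K ~ N(0, var_known)``; disease status is determined
    by ``K + R > threshold`` with independent residual ``R ~ N(0, 1 -
    var_known)`` (the remaining genetic plus environmental liability on the
    unit-total-variance scale).  Evaluated by dense-grid quadrature over K.
    """
    if not 0.0 <= var_known <= 1.0:
        raise ValueError("var_known must be in [0, 1]")
    if var_known == 0.0:
        return 0.5
    if var_known == 1.0:
        return 1.0
    sd = np.sqrt(var_known)
    sr = np.sqrt(1.0 - var_known)
    t = ndtri(1.0 - altr)
    g = np.linspace(-9.0 * sd, 9.0 * sd, n_grid)
    dens = np.exp(-0.5 * (g / sd) ** 2)  # uniform dx cancels in normalization
    q = ndtr((g - t) / sr)  # Pr(case | K = g)
    w1 = dens * q
    w0 = dens * (1.0 - q)
    w1 /= w1.sum()
    w0 /= w0.sum()
    cum0 = np.concatenate(([0.0], np.cumsum(w0)[:-1]))
    return float(np.sum(w1 * (cum0 + 0.5 * w0)))


def theoretical_max_auc(
    spec: LiabilityModel1Spec | LiabilityModel2Spec,
    n: int = 100_000,
    seed: int | np.random.Generator = 0,
    analytic: bool = False,
) -> float:
    """AUC of the exact genetic liability G as a disease classifier.

    Simulation mode draws ``n`` individuals from the model and computes the
    rank-based AUC of G against status.  The analytic mode (model 1 only)
    integrates over the (G, E) density instead and is deterministic.
    """
    if analytic:
        if not isinstance(spec, LiabilityModel1Spec):
            raise ValueError("analytic mode is available for model 1 only")
        var = spec.sigma_g**2 / (spec.sigma_g**2 + spec.sigma_e**2)
        return model1_auc_analytic(var, spec.disease.altr)
    if n < 2:
        raise ValueError("n must be >= 2")
    if isinstance(spec, LiabilityModel1Spec):
        g, _e, status = sample_model1(spec, n, seed)
    else:
        _x, g, _e, status = sample_model2(spec, n, seed)
    return _rank_auc(g, status)


# ---------------------------------------------------------------------------
# Model 2: exact distribution of the large-effect liability sum
# ---------------------------------------------------------------------------


def _locus_atoms(lam: float, p: float) -> tuple[np.ndarray, np.ndarray]:
    q = 1.0 - p
    return (
        np.array([0.0, lam, 2.0 * lam]),
        np.array([q * q, 2.0 * p * q, p * p]),
    )


def _convolve_atoms(
    v1: np.ndarray, w1: np.ndarray, v2: np.ndarray, w2: np.ndarray, res: float
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two atomic distributions, merging atoms on a value grid."""
    v = (v1[:, None] + v2[None, :]).ravel()
    w = (w1[:, None] * w2[None, :]).ravel()
    key = np.round(v / res).astype(np.int64)
    kmin = key.min()
    counts = np.bincount(key - kmin, weights=w)
    nz = np.nonzero(counts)[0]
    return (nz + kmin) * res, counts[nz]


def _sum_atoms(
    lambdas: np.ndarray, freqs: np.ndarray, res: float, skip: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of ``sum_j lambda_j X_j`` (optionally skipping one locus)."""
    vals = np.array([0.0])
    wts = np.array([1.0])
    for j, (lam, p) in enumerate(zip(lambdas, freqs)):
        if j == skip or lam == 0.0:
            continue
        lv, lw = _locus_atoms(lam, p)
        vals, wts = _convolve_atoms(vals, wts, lv, lw, res)
    return vals, wts


def _solve_threshold(
    z_vals: np.ndarray, z_wts: np.ndarray, s: float, altr: float
) -> float:
    """Threshold T with ``sum_k w_k Pr(N(z_k, s^2) > T) = altr``.

    Safeguarded Newton iteration (the survival mixture is strictly
    decreasing in T) with bisection fallback.
    """
    lo = float(z_vals.min() - 10.0 * s - 1.0)
    hi = float(z_vals.max() + 10.0 * s + 1.0)
    t = float(z_vals @ z_wts + s * ndtri(1.0 - altr))  # normal-approx start
    for _ in range(100):
        u = (t - z_vals) / s
        f = float(z_wts @ ndtr(-u)) - altr
        if abs(f) < 1e-14:
            return t
        if f > 0:
            lo = max(lo, t)
        else:
            hi = min(hi, t)
        fprime = -float(z_wts @ np.exp(-0.5 * u * u)) / (s * np.sqrt(2 * np.pi))
        step = f / fprime if fprime != 0 else np.nan
        t_new = t - step
        if not np.isfinite(t_new) or not lo < t_new < hi:
            t_new = 0.5 * (lo + hi)
        if abs(t_new - t) < 1e-13:
            return t_new
        t = t_new
    return t


def _het_rr(
    lam_i: float,
    p_i: float,
    z_vals: np.ndarray,
    z_wts: np.ndarray,
    s: float,
    altr: float,
) -> float:
    """Model-implied heterozygote relative risk of locus i.

    ``z_vals/z_wts`` is the liability-sum distribution over the *other*
    loci; ``s`` is the SD of ``G1 + E``.  The threshold is re-solved for the
    full model (including locus i) so the average lifetime risk constraint
    holds at every candidate ``lam_i``.  Locus i's own atoms are *not*
    re-rounded onto the value grid, keeping the implied relative risk a
    smooth function of ``lam_i`` for the root-finder.
    """
    lv, lw = _locus_atoms(lam_i, p_i)
    fv = (z_vals[:, None] + lv[None, :]).ravel()
    fw = (z_wts[:, None] * lw[None, :]).ravel()
    t = _solve_threshold(fv, fw, s, altr)
    p1 = float(z_wts @ ndtr((z_vals + lam_i - t) / s))
    p0 = float(z_wts @ ndtr((z_vals - t) / s))
    return p1 / p0


def solve_lambdas_model2(
    target_het_rr,
    allele_freqs,
    disease: DiseaseParams,
    tol: float = 1e-6,
    max_sweeps: int = 100,
) -> LiabilityModel2Spec:
    """Solve per-SNP liability effects matching heterozygote relative risks.

    Coordinate-wise binary searches (Gauss-Seidel sweeps in input order):
    each ``lambda_i`` is solved so that the model-implied heterozygote
    relative risk ``Pr(D | X_i = 1) / Pr(D | X_i = 0)`` equals its target,
    holding the other lambdas fixed; the polygenic SD absorbs the residual
    heritability and the threshold is re-solved at every step so the average
    lifetime risk is maintained.  Converges when the largest relative-risk
    residual drops below ``tol``.

    Uses the canonical unit-total-variance scale; solutions on any other
    scale are exact multiples (scale invariance of the liability model).
    """
    targets = np.asarray(target_het_rr, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    if np.any(targets < 1.0):
        raise ValueError("heterozygote relative-risk targets must be >= 1")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must be in (0, 1)")
    h = disease.heritability
    altr = disease.altr
    sigma_e = float(np.sqrt(1.0 - h))
    two_pq = 2.0 * p * (1.0 - p)
    k = len(targets)

    lambdas = np.zeros(k)

    def update(i: int, lam_others: np.ndarray) -> float:
        if targets[i] <= 1.0 + 1e-15:
            return 0.0
        z_vals, z_wts = _sum_atoms(lam_others, p, _GRID_RES, skip=i)
        var_others = float(two_pq @ (lam_others**2)) - two_pq[i] * lam_others[i] ** 2

        def resid(lam: float) -> float:
            var_large = var_others + two_pq[i] * lam * lam
            if var_large >= h:
                return np.inf
            s = float(np.sqrt(h - var_large + sigma_e**2))
            return _het_rr(lam, p[i], z_vals, z_wts, s, altr) - targets[i]

        hi = float(np.sqrt(max(h - var_others, 0.0) / two_pq[i])) * (1.0 - 1e-9)
        if hi <= 0 or resid(hi) < 0:
            raise ValueError(
                f"locus {i}: heterozygote relative-risk target {targets[i]} is "
                "unreachable within the heritability budget (residual "
                "heritability would be negative)"
            )
        return float(brentq(resid, 0.0, hi, xtol=1e-12, rtol=1e-12))

    converged = False
    for _sweep in range(max_sweeps):
        for i in range(k):
            lambdas[i] = update(i, lambdas)
        spec = _build_model2(lambdas, p, disease)
        resids = np.abs(implied_het_rel_risks(spec) - targets)
        if resids.max() < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"lambda solver did not converge after {max_sweeps} sweeps "
            f"(max residual {resids.max():.3g})"
        )
    return spec


def _build_model2(
    lambdas: np.ndarray, p: np.ndarray, disease: DiseaseParams
) -> LiabilityModel2Spec:
    h = disease.heritability
    var_large = float(np.sum(2.0 * p * (1.0 - p) * lambdas**2))
    if var_large > h + 1e-12:
        raise ValueError("large-effect variance exceeds the heritability budget")
    sigma_g1 = float(np.sqrt(max(h - var_large, 0.0)))
    sigma_e = float(np.sqrt(1.0 - h))
    s = float(np.hypot(sigma_g1, sigma_e))
    z_vals, z_wts = _sum_atoms(lambdas, p, _GRID_RES)
    threshold = _solve_threshold(z_vals, z_wts, s, disease.altr)
    return LiabilityModel2Spec(
        lambdas=tuple(float(v) for v in lambdas),
        allele_freqs=tuple(float(v) for v in p),
        sigma_g1=sigma_g1,
        sigma_e=sigma_e,
        threshold=threshold,
        disease=disease,
    )


def implied_het_rel_risks(spec: LiabilityModel2Spec) -> np.ndarray:
    """Heterozygote relative risks implied by a model-2 spec.

    The per-locus threshold is re-solved on the gridded liability
    distribution so the average-lifetime-risk constraint holds exactly at
    the grid resolution (the same construction the lambda solver uses).
    """
    lambdas = np.asarray(spec.lambdas)
    p = np.asarray(spec.allele_freqs)
    s = float(np.hypot(spec.sigma_g1, spec.sigma_e))
    out = np.empty(len(lambdas))
    for i in range(len(lambdas)):
        z_vals, z_wts = _sum_atoms(lambdas, p, _GRID_RES, skip=i)
        out[i] = _het_rr(lambdas[i], p[i], z_vals, z_wts, s, spec.disease.altr)
    return out


def sample_model2(
    spec: LiabilityModel2Spec, n: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``(X, G, E, status)``: genotypes, liabilities and lifetime status."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = np.asarray(spec.allele_freqs)
    x = rng.binomial(2, p, size=(n, len(p)))
    g1 = rng.normal(0.0, spec.sigma_g1, n) if spec.sigma_g1 > 0 else np.zeros(n)
    g = x @ np.asarray(spec.lambdas) + g1
    e = rng.normal(0.0, spec.sigma_e, n) if spec.sigma_e > 0 else np.zeros(n)
    status = (g + e > spec.threshold).astype(np.int8)
    return x, g, e, status


# ---------------------------------------------------------------------------
# Variance explained by known variants
# ---------------------------------------------------------------------------


def variance_explained_from_auc(
    disease: DiseaseParams, observed_auc: float, tol: float = 1e-10
) -> float:
    """Fraction of genetic variance consistent with an observed score AUC.

    Under model 1, split the genetic liability into a known component of
    variance ``f * h`` and an unknown remainder.  Returns the ``f`` at which
    the known component alone achieves ``observed_auc``; solved by monotone
    bisection with the AUC evaluated analytically.
    """
    max_auc = model1_auc_analytic(disease.heritability, disease.altr)
    if observed_auc < 0.5 - 1e-9 or observed_auc > max_auc + 1e-9:
        raise ValueError(
            f"observed AUC {observed_auc} outside [0.5, theoretical maximum "
            f"{max_auc:.4f}] for this disease"
        )
    if observed_auc <= 0.5:
        return 0.0
    if observed_auc >= max_auc:
        return 1.0
    lo, hi = 0.0, 1.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if model1_auc_analytic(mid * disease.heritability, disease.altr) < observed_auc:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def variance_explained_from_lambdas(spec: LiabilityModel2Spec) -> float:
    """Fraction of genetic variance carried by the explicit large-effect SNPs.

    ``sum_i 2 p_i (1-p_i) lambda_i^2 / h`` on the model's own scale.
    """
    lambdas = np.asarray(spec.lambdas)
    p = np.asarray(spec.allele_freqs)
    var_large = float(np.sum(2.0 * p * (1.0 - p) * lambdas**2))
    total = var_large + spec.sigma_g1**2
    return var_large / total
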