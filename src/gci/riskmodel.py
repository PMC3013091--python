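"""GCI / EGCI lifetime-risk scores and related risk arithmetic.

The Genetic Composite Index (GCI) of an individual is their lifetime disease
probability under a multiplicative independent-loci model:

    GCI = Pr(D) * prod_j lambda_{ij} / prod_j mean_j,
    mean_j = sum_k lambda_{jk} f_{jk},

where ``lambda_{ij}`` is the relative risk of the individual's level at
marker j and ``mean_j`` the frequency-weighted mean relative risk of marker
j in the population.  The normalization makes the population expectation of
the score equal the average lifetime risk Pr(D) exactly (under linkage
equilibrium).  The Environmental-Genetic Composite Index (EGCI) applies the
identical formula with categorical environmental factors included as
additional markers.

Because it is a product of free-standing relative risks, the raw score can
exceed 1 for extreme profiles; probabilities are capped at 1 and the capping
count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import MISSING, DiseaseParams, GenotypeMatrix, Marker

__all__ = [
    "RiskProfile",
    "mean_relative_risk",
    "gci_score",
    "egci_score",
    "cohort_scores",
    "relative_error",
    "lifetime_risk_from_incidence",
]


@dataclass(frozen=True)
class RiskProfile:
    """One individual's observed levels over a marker panel."""

    marker_levels: tuple[int, ...]
    markers: tuple[Marker, ...]
    disease: DiseaseParams

    def __post_init__(self) -> None:
        if len(self.marker_levels) != len(self.markers):
            raise ValueError("marker_levels and markers length mismatch")
        for lv, m in zip(self.marker_levels, self.markers):
            if lv != MISSING and not 0 <= lv < m.n_levels:
                raise ValueError(f"level {lv} invalid for marker {m.id}")


def mean_relative_risk(marker: Marker) -> float:
    """Frequency-weighted mean relative risk ``sum_k lambda_jk f_jk``."""
    return float(np.dot(marker.rel_risks, marker.freqs))


def _score(levels: Sequence[int], markers: Sequence[Marker], altr: float) -> float:
    # log-space product: robust for large panels
    log_num = 0.0
    log_den = 0.0
    for lv, m in zip(levels, markers):
        if lv == MISSING:
            continue  # missing genotype contributes relative risk 1
        log_num += np.log(m.rel_risks[lv])
        log_den += np.log(mean_relative_risk(m))
    return float(altr * np.exp(log_num - log_den))


def gci_score(profile: RiskProfile, cap: bool = True) -> float:
    """GCI lifetime-risk probability of one individual (genetic markers).

    With ``cap=True`` (default) scores above 1 are truncated to 1.
    """
    if any(m.kind != "genetic" for m in profile.markers):
        raise ValueError("gci_score accepts genetic markers only; use egci_score")
    s = _score(profile.marker_levels, profile.markers, profile.disease.altr)
    return min(s, 1.0) if cap else s


def egci_score(profile: RiskProfile, cap: bool = True) -> float:
    """EGCI lifetime-risk probability (genetic + environmental markers).

    Identical formula to :func:`gci_score`; environmental factor levels are
    treated exactly like marker genotypes.
    """
    s = _score(profile.marker_levels, profile.markers, profile.disease.altr)
    return min(s, 1.0) if cap else s


def cohort_scores(
    values: np.ndarray,
    markers: Sequence[Marker],
    disease: DiseaseParams,
    columns: Sequence[int] | None = None,
    cap: bool = True,
) -> np.ndarray:
    """Vectorized (E)GCI scores for a cohort.

    Parameters
    ----------
    values:
        ``(n, k)`` level-index array (a :class:`GenotypeMatrix` ``values``
        field); :data:`~gci.core_io.MISSING` entries contribute relative
        risk 1.
    markers:
        The ``k`` markers matching the columns of ``values``.
    columns:
        Optional subset of column indices to score (e.g. genetic-only GCI on
        a cohort that also carries environmental columns).
    """
    if isinstance(values, GenotypeMatrix):
        values = values.values
    values = np.asarray(values)
    idx = range(len(markers)) if columns is None else columns
    log_rr = np.zeros(values.shape[0])
    log_norm = 0.0
    for j in idx:
        m = markers[j]
        table = np.log(np.asarray(m.rel_risks, dtype=float))
        col = values[:, j]
        safe = np.where(col == MISSING, 0, col)
        contrib = table[safe]
        log_rr += np.where(col == MISSING, 0.0, contrib)
        log_norm += np.log(mean_relative_risk(m))
    scores = disease.altr * np.exp(log_rr - log_norm)
    return np.minimum(scores, 1.0) if cap else scores


def relative_error(estimated: float, true_risk: float) -> float:
    """Absolute relative error ``|estimated - true| / true``."""
    if true_risk <= 0:
        raise ValueError("true_risk must be positive")
    return abs(estimated - true_risk) / true_risk


def lifetime_risk_from_incidence(
    annual_new_cases: Sequence[float] | float,
    annual_births: Sequence[float] | float,
) -> float:
    """Average lifetime risk from steady-state incidence data.

    Under a fixed population size with everyone reaching a maximal lifespan,
    each birth cohort eventually accrues the annual number of new cases, so

        ALTR = sum_strata(annual new cases) / sum_strata(annual births).

    Strata (gender/ethnicity) are pooled by summing numerators and
    denominators.
    """
    cases = np.atleast_1d(np.asarray(annual_new_cases, dtype=float))
    births = np.atleast_1d(np.asarray(annual_births, dtype=float))
    if np.any(births <= 0):
        raise ValueError("annual births must be positive in every stratum")
    if np.any(cases < 0):
        raise ValueError("annual case counts must be nonnegative")
    return float(cases.sum() / births.sum())
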