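"""Domain types and table I/O for marker summary statistics.

A :class:`Marker` holds per-genotype (or per-environmental-level) relative
risks and population frequencies for one risk locus.  Genetic markers use the
risk-allele-count coding 0/1/2 with the zero-copy genotype as baseline
(relative risk fixed at 1).  Environmental factors are ordinary markers whose
"levels" are exposure categories; the first level is the baseline.

Two tab-separated dialects are supported for marker tables:

* long format with header ``id  level  rel_risk  freq`` (one row per level);
* compact genetic format with header ``id  rr_hom  rr_het  freq_hom
  freq_het`` (one row per SNP; the non-risk homozygote frequency is
  ``1 - freq_hom - freq_het``).

The published summary tables for Type 2 Diabetes, Crohn's disease and
Rheumatoid Arthritis ship with the package and are exposed through
:func:`load_fixtures`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Marker",
    "DiseaseParams",
    "GenotypeMatrix",
    "MISSING",
    "read_marker_table",
    "write_marker_table",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_disease_params",
    "load_fixtures",
]

#: Sentinel level index for a missing genotype/level observation.
MISSING: int = -1

_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class Marker:
    """One risk locus or categorical environmental factor.

    Parameters
    ----------
    id:
        Identifier (dbSNP rsID for SNPs, factor name for environmental
        variables).
    kind:
        ``"genetic"`` or ``"environmental"``.
    levels:
        Ordered level labels.  Level 0 is the baseline (relative risk 1).
        Genetic markers must have exactly three levels (0/1/2 risk alleles).
    rel_risks:
        Per-level relative risk versus the baseline level.
    freqs:
        Per-level population frequency; must sum to 1.
    """

    id: str
    kind: str
    levels: tuple[str, ...]
    rel_risks: tuple[float, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("genetic", "environmental"):
            raise ValueError(f"marker {self.id}: unknown kind {self.kind!r}")
        n = len(self.levels)
        if len(self.rel_risks) != n or len(self.freqs) != n:
            raise ValueError(f"marker {self.id}: field lengths disagree")
        if self.kind == "genetic" and n != 3:
            raise ValueError(f"genetic marker {self.id} must have 3 levels, got {n}")
        if abs(self.rel_risks[0] - 1.0) > 1e-12:
            raise ValueError(f"marker {self.id}: baseline relative risk must be 1.0")
        if any(r <= 0 for r in self.rel_risks):
            raise ValueError(f"marker {self.id}: relative risks must be positive")
        if any(f < 0 for f in self.freqs):
            raise ValueError(f"marker {self.id}: negative frequency")
        total = sum(self.freqs)
        if abs(total - 1.0) > _FREQ_TOL:
            raise ValueError(
                f"marker {self.id}: frequencies sum to {total!r}, expected 1"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def risk_allele_freq(self) -> float:
        """Risk-allele frequency implied by the genotype frequencies.

        Only meaningful for genetic markers: ``f(RR) + f(RN)/2``.
        """
        if self.kind != "genetic":
            raise ValueError("risk_allele_freq is defined for genetic markers only")
        return self.freqs[2] + 0.5 * self.freqs[1]

    def normalized(self) -> "Marker":
        """Return a copy with frequencies rescaled to sum exactly to 1."""
        total = sum(self.freqs)
        return Marker(
            self.id,
            self.kind,
            self.levels,
            self.rel_risks,
            tuple(f / total for f in self.freqs),
        )


@dataclass(frozen=True)
class DiseaseParams:
    """Average lifetime risk and heritability of one condition."""

    name: str
    altr: float
    heritability: float

    def __post_init__(self) -> None:
        if not 0.0 < self.altr < 1.0:
            raise ValueError(f"{self.name}: average lifetime risk must be in (0,1)")
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError(f"{self.name}: heritability must be in [0,1]")


@dataclass
class GenotypeMatrix:
    """Per-individual, per-marker observed level indices.

    ``values`` is an ``(n_individuals, n_markers)`` integer array of level
    indices; :data:`MISSING` marks a missing observation.
    """

    individual_ids: list[str]
    marker_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError("GenotypeMatrix shape inconsistent with id lists")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def n_missing(self) -> int:
        return int(np.sum(self.values == MISSING))

    def validate_against(self, markers: Sequence[Marker]) -> None:
        by_id = {m.id: m for m in markers}
        for j, mid in enumerate(self.marker_ids):
            if mid not in by_id:
                raise ValueError(f"unknown marker column {mid!r}")
            col = self.values[:, j]
            bad = (col != MISSING) & ((col < 0) | (col >= by_id[mid].n_levels))
            if np.any(bad):
                i = int(np.argmax(bad))
                raise ValueError(
                    f"individual {self.individual_ids[i]!r}, marker {mid!r}: "
                    f"level index {int(col[i])} out of range"
                )


# ---------------------------------------------------------------------------
# Table readers / writers
# ---------------------------------------------------------------------------

_COMPACT_COLS = ["id", "rr_hom", "rr_het", "freq_hom", "freq_het"]
_LONG_COLS = ["id", "level", "rel_risk", "freq"]


def read_marker_table(
    path: str | Path,
    kind: str = "genetic",
    normalize_freqs: bool = False,
) -> list[Marker]:
    """Read a TSV marker table in either the long or the compact dialect.

    Parameters
    ----------
    path:
        Tab-separated file.  The dialect is detected from the header.
    kind:
        Marker kind to assign (``genetic`` / ``environmental``).
    normalize_freqs:
        If true, rescale level frequencies to sum to 1 before validation
        (for published tables whose printed frequencies carry rounding error).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    cols = list(df.columns)
    markers: list[Marker] = []
    if cols == _COMPACT_COLS:
        if kind != "genetic":
            raise ValueError("compact marker tables are genetic-only")
        for _, row in df.iterrows():
            freq_nn = 1.0 - row.freq_hom - row.freq_het
            if freq_nn < -_FREQ_TOL:
                raise ValueError(
                    f"marker {row.id}: genotype frequencies sum to "
                    f"{row.freq_hom + row.freq_het} > 1"
                )
            markers.append(
                Marker(
                    id=str(row.id),
                    kind="genetic",
                    levels=("NN", "RN", "RR"),
                    rel_risks=(1.0, float(row.rr_het), float(row.rr_hom)),
                    freqs=(max(freq_nn, 0.0), float(row.freq_het), float(row.freq_hom)),
                )
            )
    elif cols == _LONG_COLS:
        for mid, grp in df.groupby("id", sort=False):
            m = Marker(
                id=str(mid),
                kind=kind,
                levels=tuple(str(x) for x in grp.level),
                rel_risks=tuple(float(x) for x in grp.rel_risk),
                freqs=tuple(float(x) for x in grp.freq)
                if not normalize_freqs
                else tuple(float(x) / grp.freq.sum() for x in grp.freq),
            )
            markers.append(m)
    else:
        raise ValueError(
            f"unrecognized marker table header {cols!r}; expected "
            f"{_LONG_COLS} or {_COMPACT_COLS}"
        )
    if normalize_freqs and cols == _COMPACT_COLS:
        markers = [m.normalized() for m in markers]
    ids = [m.id for m in markers]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate marker id(s): {dup}")
    return markers


def write_marker_table(markers: Sequence[Marker], path: str | Path) -> None:
    """Write markers in the long TSV dialect (lossless for both kinds)."""
    rows = [
        {"id": m.id, "level": lv, "rel_risk": rr, "freq": f}
        for m in markers
        for lv, rr, f in zip(m.levels, m.rel_risks, m.freqs)
    ]
    pd.DataFrame(rows, columns=_LONG_COLS).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(
    path: str | Path, markers: Sequence[Marker] | None = None
) -> GenotypeMatrix:
    """Read a TSV genotype matrix (first column individual id).

    Missing entries may be encoded as empty fields, ``NA`` or ``-1``.  When
    ``markers`` is given, column names and level indices are validated.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""])
    ind_ids = [str(x) for x in df.iloc[:, 0]]
    marker_ids = list(df.columns[1:])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    values = np.where(np.isnan(values), MISSING, values).astype(np.int64)
    gm = GenotypeMatrix(ind_ids, marker_ids, values)
    if markers is not None:
        gm.validate_against(markers)
    return gm


def write_genotype_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(gm.values, columns=gm.marker_ids)
    df.insert(0, "individual", gm.individual_ids)
    df.to_csv(path, sep="\t", index=False)


def read_disease_params(path: str | Path) -> DiseaseParams:
    """Read a JSON disease-parameter config ``{name, altr, heritability}``."""
    with open(path) as fh:
        obj = json.load(fh)
    return DiseaseParams(obj["name"], float(obj["altr"]), float(obj["heritability"]))


# ---------------------------------------------------------------------------
# Bundled fixtures (published summary tables)
# ---------------------------------------------------------------------------

_GENETIC_FIXTURES = {
    "t2d_table1": ("t2d_table1.tsv", "t2d"),
    "crohns_table1": ("crohns_table1.tsv", "crohns"),
    "ra_table1": ("ra_table1.tsv", "ra"),
    "t2d_table6": ("t2d_table6.tsv", "t2d"),
}
_ENV_FIXTURES = {
    "t2d_env": ("t2d_env.tsv", "t2d"),
    "crohns_env": ("crohns_env.tsv", "crohns"),
    "ra_env": ("ra_env.tsv", "ra"),
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gci").joinpath("data", name)))


def load_disease_params() -> dict[str, DiseaseParams]:
    """Bundled heritability / average-lifetime-risk parameters by disease key."""
    with open(_data_path("disease_params.json")) as fh:
        raw = json.load(fh)
    return {
        k: DiseaseParams(v["name"], v["altr"], v["heritability"])
        for k, v in raw.items()
    }


def load_fixtures() -> dict[str, tuple[list[Marker], DiseaseParams]]:
    """Load the bundled published marker tables.

    Returns a mapping from fixture name to ``(markers, disease_params)``.
    Genetic fixtures keep the printed genotype frequencies verbatim;
    environmental fixtures are rescaled to sum exactly to 1 (the printed
    proportions carry up to 1% rounding error).
    """
    params = load_disease_params()
    out: dict[str, tuple[list[Marker], DiseaseParams]] = {}
    for name, (fname, dkey) in _GENETIC_FIXTURES.items():
        out[name] = (read_marker_table(_data_path(fname), "genetic"), params[dkey])
    for name, (fname, dkey) in _ENV_FIXTURES.items():
        out[name] = (
            read_marker_table(_data_path(fname), "environmental", normalize_freqs=True),
            params[dkey],
        )
    return out


def missing_as_baseline(
    gm: GenotypeMatrix, markers: Sequence[Marker]
) -> tuple[np.ndarray, int]:
    """Replace missing level indices by the baseline level (relative risk 1).

    Returns the cleaned value array and the number of replacements; a warning
    is emitted when any genotype was missing.
    """
    n_miss = gm.n_missing()
    if n_miss:
        warnings.warn(
            f"{n_miss} missing genotype(s) treated as baseline (relative risk 1)",
            stacklevel=2,
        )
    return np.where(gm.values == MISSING, 0, gm.values), n_miss
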