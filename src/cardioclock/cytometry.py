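"""Ploidy, nucleation and sort-purity arithmetic for cardiomyocyte cytometry.

Flow cytometry on PCM1⁺ nuclei yields per-sample ploidy-class fractions;
image cytometry on intact cells yields joint (nuclei-per-cell × nuclear
ploidy) tables.  This module converts those summaries into the scalar
quantities the turnover model consumes:

* degree of nuclear ploidy — mean genome copies per nucleus as a percentage
  of a purely diploid reference (100% = all 2n, 200% = all 4n);
* binucleated fraction and the mononucleated-diploid fraction;
* mean genome content per cell in diploid-genome units;
* the DNA-mass purity of a FACS sort with polyploid contaminants;
* isometric log-ratio (ilr) coordinates for compositional statistics.

Ploidy classes are powers of two from 2n to 16n (class c carries c/2 diploid
genome units); cells are mono- or binucleated — higher nucleation classes are
outside the data model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "PLOIDY_CLASSES",
    "PloidyProfile",
    "NucleationPloidyTable",
    "SortPurity",
    "degree_of_nuclear_ploidy",
    "dna_purity",
    "binucleated_fraction",
    "mononucleated_diploid_fraction",
    "mean_genome_per_cell",
    "ilr_transform",
    "ploidy_profile_from_csv",
    "nucleation_table_from_csv",
]

PLOIDY_CLASSES = (2, 4, 8, 16)
_FRACTION_TOL = 1e-9


def _parse_ploidy_class(key) -> int:
    """Normalize '4n' / '4N' / 4 to the integer ploidy 4."""
    if isinstance(key, str):
        key = key.strip().lower().rstrip("n")
    try:
        c = int(key)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"unrecognized ploidy class {key!r}") from exc
    if c not in PLOIDY_CLASSES:
        raise ValueError(
            f"ploidy class {c}n outside supported classes "
            f"{{{', '.join(f'{k}n' for k in PLOIDY_CLASSES)}}}"
        )
    return c


def _check_fractions(values, what: str) -> None:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{what}: at least one class required")
    if np.any(arr < 0):
        raise ValueError(f"{what}: fractions must be non-negative")
    if abs(arr.sum() - 1.0) > _FRACTION_TOL:
        raise ValueError(f"{what}: fractions sum to {arr.sum()!r}, expected 1")


@dataclass(frozen=True)
class PloidyProfile:
    """Fractions of nuclei per ploidy class (2n, 4n, 8n, 16n)."""

    class_fractions: Mapping["int | str", float]

    def __post_init__(self) -> None:
        norm = {_parse_ploidy_class(k): float(v) for k, v in self.class_fractions.items()}
        if len(norm) != len(self.class_fractions):
            raise ValueError("duplicate ploidy class after normalization")
        _check_fractions(list(norm.values()), "PloidyProfile")
        object.__setattr__(self, "class_fractions", norm)

    def fraction(self, ploidy_class: "int | str") -> float:
        return self.class_fractions.get(_parse_ploidy_class(ploidy_class), 0.0)


@dataclass(frozen=True)
class NucleationPloidyTable:
    """Joint fractions of cardiomyocytes over (nuclei per cell, nuclear ploidy).

    Keys are ``(nuclei, class)`` with nuclei ∈ {1, 2}; the mono-/binucleated
    dichotomy matches how human cardiomyocyte nucleation is quantified.
    """

    joint_fractions: Mapping[Tuple[int, "int | str"], float]

    def __post_init__(self) -> None:
        norm: dict[tuple[int, int], float] = {}
        for (nuclei, cls), v in self.joint_fractions.items():
            nuclei = int(nuclei)
            if nuclei not in (1, 2):
                raise ValueError(
                    f"nuclei-per-cell must be 1 or 2, got {nuclei} "
                    "(higher nucleation classes are outside the data model)"
                )
            key = (nuclei, _parse_ploidy_class(cls))
            if key in norm:
                raise ValueError(f"duplicate joint class {key}")
            norm[key] = float(v)
        _check_fractions(list(norm.values()), "NucleationPloidyTable")
        object.__setattr__(self, "joint_fractions", norm)

    def fraction(self, nuclei: int, ploidy_class: "int | str") -> float:
        return self.joint_fractions.get((int(nuclei), _parse_ploidy_class(ploidy_class)), 0.0)

    def nuclear_margin(self) -> PloidyProfile:
        """Ploidy profile of *nuclei* implied by the cell-level joint table."""
        weights: dict[int, float] = {}
        for (nuclei, cls), f in self.joint_fractions.items():
            weights[cls] = weights.get(cls, 0.0) + nuclei * f
        total = sum(weights.values())
        return PloidyProfile({c: w / total for c, w in weights.items()})

    def mean_nuclei_per_cell(self) -> float:
        return sum(n * f for (n, _), f in self.joint_fractions.items())


@dataclass(frozen=True)
class SortPurity:
    """FACS sort composition: target nuclei plus contaminating populations.

    ``target_fraction`` f_x and each contaminant fraction must sum to 1; DNA
    contents are in n-units (diploid nuclei have content 2), reflecting that
    polyploid contaminants contribute disproportionate DNA mass.
    """

    target_fraction: float
    target_dna_content: float = 2.0
    contaminants: Sequence[Tuple[float, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        cont = tuple((float(f), float(c)) for f, c in self.contaminants)
        object.__setattr__(self, "contaminants", cont)
        fracs = [self.target_fraction] + [f for f, _ in cont]
        if any(f < 0 for f in fracs):
            raise ValueError("fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > _FRACTION_TOL:
            raise ValueError(
                f"target + contaminant fractions sum to {sum(fracs)!r}, expected 1"
            )
        if self.target_dna_content <= 0 or any(c <= 0 for _, c in cont):
            raise ValueError("DNA contents must be positive")
        if self.target_fraction <= 0:
            raise ValueError("target fraction must be positive")


def degree_of_nuclear_ploidy(profile: PloidyProfile) -> float:
    """Mean genome copies per nucleus, in percent of a purely diploid reference.

    100% corresponds to only diploid (2n) nuclei, 200% to only tetraploid
    (4n) nuclei: ``100 × Σ_c fraction(c) × c/2``.
    """
    return 100.0 * sum(f * (c / 2.0) for c, f in profile.class_fractions.items())


def dna_purity(purity: SortPurity) -> float:
    """Fraction of extracted DNA mass originating from the target population.

    Purity_x = f_x·c_x / (f_x·c_x + Σ_i f_i·c_i): a 90%-pure sort whose
    contaminants are polyploid yields a DNA purity below 90% because the
    contaminating nuclei carry more DNA each.
    """
    target_mass = purity.target_fraction * purity.target_dna_content
    total_mass = target_mass + sum(f * c for f, c in purity.contaminants)
    return target_mass / total_mass


def binucleated_fraction(table: NucleationPloidyTable) -> float:
    """Fraction of cardiomyocytes with two nuclei (marginal over ploidy)."""
    return sum(f for (n, _), f in table.joint_fractions.items() if n == 2)


def mononucleated_diploid_fraction(table: NucleationPloidyTable) -> float:
    """Joint fraction of mononucleated diploid (1 × 2n) cardiomyocytes."""
    return table.fraction(1, 2)


def mean_genome_per_cell(table: NucleationPloidyTable) -> float:
    """Mean genome content per cardiomyocyte in diploid-genome units.

    Each cell contributes nuclei-per-cell × (class/2) genome copies; a purely
    mononucleated-diploid population scores 1.0, binucleated tetraploid 4.0.
    """
    return sum(n * (c / 2.0) * f for (n, c), f in table.joint_fractions.items())


def ilr_transform(composition) -> np.ndarray:
    """Isometric log-ratio coordinates of a k-part composition.

    Uses the sequential-binary-partition basis: coordinate j (1-based) is
    ``sqrt(j/(j+1)) · ln(gmean(x_1..x_j) / x_{j+1})``.  The map is an isometry
    between the Aitchison simplex metric and Euclidean space, so downstream
    distance-based statistics are basis-independent.

    Parts must be strictly positive; zero parts raise with a pointer to apply
    an explicit, declared pseudo-count upstream rather than silently imputing
    one here.
    """
    x = np.asarray(composition, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("composition must be a 1-D vector with ≥2 parts")
    if np.any(x <= 0):
        raise ValueError(
            "composition parts must be strictly positive; replace zeros with a "
            "declared pseudo-count before transforming"
        )
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValueError(f"composition must sum to 1, got {x.sum()!r}")
    logx = np.log(x)
    j = np.arange(1, x.size)
    gmean_log = np.cumsum(logx)[:-1] / j
    return np.sqrt(j / (j + 1.0)) * (gmean_log - logx[1:])


def ploidy_profile_from_csv(source) -> PloidyProfile:
    """Read a `class,fraction` CSV (classes 2n/4n/8n/16n) into a profile."""
    df = pd.read_csv(source, comment="#")
    if not {"class", "fraction"} <= set(df.columns):
        raise ValueError("ploidy profile CSV needs columns class,fraction")
    return PloidyProfile(dict(zip(df["class"], df["fraction"].astype(float))))


def nucleation_table_from_csv(source) -> NucleationPloidyTable:
    """Read a `nuclei,class,fraction` CSV into a joint nucleation×ploidy table."""
    df = pd.read_csv(source, comment="#")
    if not {"nuclei", "class", "fraction"} <= set(df.columns):
        raise ValueError("joint table CSV needs columns nuclei,class,fraction")
    return NucleationPloidyTable(
        {(int(n), c): float(f) for n, c, f in zip(df["nuclei"], df["class"], df["fraction"])}
    )
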