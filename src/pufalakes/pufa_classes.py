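"""Quartile-based ordinal PUFA classification of taxa.

Each taxon receives, per fatty acid, an ordinal content class 1–5: class 1
marks "not detected" (zero mean mass fraction) and classes 2–5 correspond to
the four quartile intervals of the non-degenerate mass-fraction distribution
observed across the taxon set.  Boundaries are the sample quartiles of the
taxon mean mass fractions (zeros included), estimated by linear interpolation
of order statistics (position ``p·(n−1)+1`` on the sorted sample — numpy's
default "linear"/type-7 rule).  Intervals are lower-inclusive: class 5 is
``value ≥ q3``.

Boundaries are always recomputed from the data, never hard-coded.  Because
published class tables round means to one decimal, a derived class can
disagree with a printed class when the rounded mean sits within rounding
distance of a boundary; :func:`classify_all` reports such cases explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .data_model import PUFAS, TaxonPufaProfile

#: Half of one printed decimal — the rounding margin used when judging whether
#: a disagreement with a printed class is attributable to boundary rounding.
ROUNDING_MARGIN = 0.05


@dataclass(frozen=True)
class ClassBoundaries:
    """Quartile cut points for one PUFA, with a lower-inclusive convention."""

    pufa: str
    q1: float
    q2: float
    q3: float
    convention: str = "lower-inclusive"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.q1) and math.isfinite(self.q2) and math.isfinite(self.q3)):
            raise ValueError("class boundaries must be finite")
        if not 0.0 <= self.q1 <= self.q2 <= self.q3:
            raise ValueError("class boundaries must satisfy 0 <= q1 <= q2 <= q3")


@dataclass(frozen=True)
class ClassMismatch:
    """A taxon whose derived class differs from the printed class."""

    taxon: str
    pufa: str
    mean: float
    printed_class: int
    derived_class: int
    distance_to_boundary: float
    is_boundary_case: bool  # printed mean within ROUNDING_MARGIN of a boundary


@dataclass(frozen=True)
class ClassificationResult:
    boundaries: dict[str, ClassBoundaries]
    profiles: list[TaxonPufaProfile]  # classes replaced by derived classes
    mismatches: list[ClassMismatch]


def compute_boundaries(values: Iterable[float], pufa: str) -> ClassBoundaries:
    """Sample quartiles of mass-fraction values (zeros included)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 4:
        raise ValueError("need at least 4 values to compute quartile boundaries")
    if np.any(~np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError("mass fractions must be finite and non-negative")
    q1, q2, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation (type 7)
    return ClassBoundaries(pufa=pufa, q1=float(q1), q2=float(q2), q3=float(q3))


def assign_class(value: float, boundaries: ClassBoundaries) -> int:
    """Ordinal class of a mass fraction under lower-inclusive boundaries.

    0 → 1 (not detected); (0, q1) → 2; [q1, q2) → 3; [q2, q3) → 4; [q3, ∞) → 5.
    """
    if not math.isfinite(value) or value < 0:
        raise ValueError("mass fraction must be finite and non-negative")
    if value == 0.0:
        return 1
    if value < boundaries.q1:
        return 2
    if value < boundaries.q2:
        return 3
    if value < boundaries.q3:
        return 4
    return 5


def classify_all(profiles: Sequence[TaxonPufaProfile]) -> ClassificationResult:
    """Derive boundaries and classes for every taxon × PUFA.

    Boundaries are computed per PUFA over all taxon mean mass fractions.  The
    consistency report lists every taxon whose derived class differs from the
    class carried on the input profile, flagging whether the (rounded) input
    mean lies within :data:`ROUNDING_MARGIN` of a derived boundary.
    """
    if len(profiles) < 4:
        raise ValueError("need at least 4 profiles to classify")
    boundaries = {
        pufa: compute_boundaries([p.mean_for(pufa) for p in profiles], pufa)
        for pufa in PUFAS
    }
    classified: list[TaxonPufaProfile] = []
    mismatches: list[ClassMismatch] = []
    for profile in profiles:
        derived = {}
        for pufa in PUFAS:
            b = boundaries[pufa]
            mean = profile.mean_for(pufa)
            derived[pufa] = assign_class(mean, b)
            printed = profile.class_for(pufa)
            if derived[pufa] != printed:
                distance = min(abs(mean - q) for q in (b.q1, b.q2, b.q3))
                mismatches.append(
                    ClassMismatch(
                        taxon=profile.taxon,
                        pufa=pufa,
                        mean=mean,
                        printed_class=printed,
                        derived_class=derived[pufa],
                        distance_to_boundary=distance,
                        is_boundary_case=distance <= ROUNDING_MARGIN,
                    )
                )
        classified.append(
            replace(
                profile,
                class_ara=derived["ara"],
                class_epa=derived["epa"],
                class_dha=derived["dha"],
            )
        )
    return ClassificationResult(boundaries=boundaries, profiles=classified, mismatches=mismatches)
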