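"""Circulating T cell totals per donor and projection targets.

Richness is extrapolated not to an arbitrary depth but to the donor's own
circulating cell numbers, combining (a) lymphocytes per µL from a CBC,
(b) subset fractions from flow cytometry, and (c) total blood volume from
Nadler's anthropometric formula. The extrapolation target is 1/100 of the
subset total (richness beyond that depth is computationally out of reach
for rarefaction-model fitting, so the published analysis projects to 1%
of circulating cells).

Heights are metres internally; Nadler's formula is cubic in height, so a
silent cm/m mixup is the main hazard — conversion is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

MICROLITRES_PER_LITRE = 1_000_000

#: default projection factor: extrapolate to 1% of circulating cells
DEFAULT_PROJECTION_FACTOR = 1.0 / 100

#: canonical subsets: CD4/CD8 × naive/memory
SUBSETS = ("CD4_naive", "CD4_memory", "CD8_naive", "CD8_memory")

# Nadler blood-volume constants (litres; height in metres, weight in kg)
_NADLER = {
    "male": (0.3669, 0.03219, 0.6041),
    "female": (0.3561, 0.03308, 0.1833),
}


class CellAccountingError(ValueError):
    pass


@dataclass
class DonorProfile:
    """Anthropometrics, CBC and subset fractions for one donor visit."""

    donor: str
    visit: int
    age: float
    sex: str  # "male" | "female"
    height_m: float
    weight_kg: float
    lymphocytes_per_ul: float
    subset_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in _NADLER:
            raise CellAccountingError(f"sex must be male/female, "
                                      f"got {self.sex!r}")
        if self.height_m <= 0 or self.weight_kg <= 0:
            raise CellAccountingError("height and weight must be positive")
        if self.lymphocytes_per_ul <= 0:
            raise CellAccountingError("lymphocyte count must be positive")
        for name, frac in self.subset_fractions.items():
            if not 0.0 <= frac <= 1.0:
                raise CellAccountingError(
                    f"subset fraction {name}={frac} outside [0, 1]")


def nadler_volume(height_m: float, weight_kg: float, sex: str) -> float:
    """Total blood volume in litres by Nadler's formula.

    male:   0.3669·h³ + 0.03219·w + 0.6041
    female: 0.3561·h³ + 0.03308·w + 0.1833
    """
    if sex not in _NADLER:
        raise CellAccountingError(f"sex must be male/female, got {sex!r}")
    if height_m <= 0 or weight_kg <= 0:
        raise CellAccountingError("height and weight must be positive")
    a, b, c = _NADLER[sex]
    return a * height_m ** 3 + b * weight_kg + c


def cm_to_m(height_cm: float) -> float:
    return height_cm / 100.0


def blood_volume(profile: DonorProfile) -> float:
    return nadler_volume(profile.height_m, profile.weight_kg, profile.sex)


def subset_total(profile: DonorProfile, subset: str) -> float:
    """Cells of one subset in the donor's total blood.

    lymphocytes/µL × subset fraction × blood volume in µL.
    """
    if subset not in profile.subset_fractions:
        raise CellAccountingError(
            f"profile has no fraction for subset {subset!r}")
    volume_ul = blood_volume(profile) * MICROLITRES_PER_LITRE
    return (profile.lymphocytes_per_ul
            * profile.subset_fractions[subset] * volume_ul)


def projection_target(total_cells: float,
                      factor: float = DEFAULT_PROJECTION_FACTOR) -> int:
    """Target population for richness extrapolation.

    ``round(total_cells × factor)`` with round-half-even, applied only at
    this final step.
    """
    if total_cells < 1:
        raise CellAccountingError("total_cells must be >= 1")
    if factor <= 0:
        raise CellAccountingError("projection factor must be positive")
    return round(total_cells * factor)


def population_from_projection(projected_cells: float,
                               factor: float = DEFAULT_PROJECTION_FACTOR
                               ) -> float:
    """Invert :func:`projection_target`: scale a 1%-of-blood quantity back
    to the whole-blood population (used to turn richness projected to 1%
    of circulating cells into a whole-blood lower bound)."""
    if factor <= 0:
        raise CellAccountingError("projection factor must be positive")
    return projected_cells / factor
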