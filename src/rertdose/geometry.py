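"""Equivalent-sphere geometry for tumour volumes.

Gross tumour volumes (GTV) in cc are converted to the radius of a sphere of
equal volume, V = (4/3) * pi * r^3, giving a comparable one-dimensional size
measure; the same formula defines volume cut-offs for dichotomising a cohort
by tumour size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import DataError, ValidationError


@dataclass(frozen=True)
class SphericalEquivalent:
    """A tumour volume and the radius of the equal-volume sphere."""

    volume_cc: float
    radius_cm: float

    def __post_init__(self):
        if abs(self.volume_cc - sphere_volume(self.radius_cm)) > 1e-9:
            raise ValidationError("volume_cc and radius_cm are inconsistent")


def sphere_volume(radius_cm: float) -> float:
    """Volume in cc of a sphere with the given radius in cm."""
    if radius_cm < 0:
        raise ValidationError(f"radius must be non-negative, got {radius_cm}")
    return (4.0 / 3.0) * math.pi * radius_cm**3


def sphere_radius(volume_cc: float) -> float:
    """Radius in cm of a sphere with the given volume in cc."""
    if volume_cc < 0:
        raise ValidationError(f"volume must be non-negative, got {volume_cc}")
    return (3.0 * volume_cc / (4.0 * math.pi)) ** (1.0 / 3.0)


def spherical_equivalent(volume_cc: float) -> SphericalEquivalent:
    return SphericalEquivalent(volume_cc, sphere_radius(volume_cc))


def volume_dichotomy(
    volumes_cc: Mapping[str, float | None],
    r_cut_cm: float,
    exclusions: Iterable[str] = (),
) -> tuple[list[str], list[str]]:
    """Split patients into small / large tumour groups at a radius cut-off.

    The cut-off volume is ``sphere_volume(r_cut_cm)``; patients strictly
    below it form the small group, patients at or above it the large group
    (a volume exactly on the boundary counts as large).  Excluded patients
    (e.g. distant, distinct lesions that make a single-volume summary
    meaningless) belong to neither group.

    Parameters
    ----------
    volumes_cc:
        Mapping from patient id to re-treatment GTV volume in cc; ``None``
        is allowed only for excluded patients.
    """
    excl = set(exclusions)
    v_cut = sphere_volume(r_cut_cm)
    small, large = [], []
    for pid, vol in volumes_cc.items():
        if pid in excl:
            continue
        if vol is None:
            raise DataError(f"patient {pid} has no volume and no exclusion flag")
        (large if vol >= v_cut else small).append(pid)
    return small, large
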