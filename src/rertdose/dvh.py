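"""Dose-volume histogram (DVH) data model and manipulation.

A DVH summarises the dose distribution inside a contoured structure.  The
cumulative form gives, for each dose level ``D``, the fraction of the
structure volume receiving at least ``D``; the differential form gives the
volume fraction falling in each dose bin.  All volumes here are relative
(fractions of the structure volume); the absolute structure volume in cc is
carried as optional metadata only.

The module also handles ingestion of sparse digitised points, as produced
when DVH curves are recovered from printed plan hardcopies: the points are
sorted, clipped and projected onto the nearest monotone curve before being
treated as a cumulative DVH.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

CUMULATIVE = "cumulative"
DIFFERENTIAL = "differential"

#: threshold (fraction of structure volume) below which a bin counts as empty
#: when locating near-minimum and near-maximum doses
VOLUME_EPS = 1e-6

#: default resampling resolution in Gy
DEFAULT_BIN_GY = 0.1

_CSV_COLUMNS = [
    "patient_id",
    "course",
    "structure",
    "mode",
    "dose_gy",
    "volume_fraction",
    "absolute_volume_cc",
]


@dataclass(frozen=True)
class DoseVolumeHistogram:
    """A relative-volume DVH for one structure.

    Parameters
    ----------
    structure_name:
        Label of the contoured structure (e.g. ``"optic_chiasm"``).
    mode:
        ``"cumulative"`` — ``volume[j]`` is the fraction receiving at least
        ``dose_edges[j]`` (one value per edge) — or ``"differential"`` —
        ``volume[i]`` is the fraction in bin ``[dose_edges[i],
        dose_edges[i+1])`` (one value per bin).
    dose_edges:
        Strictly increasing dose values in Gy, starting at 0.
    volume:
        Relative volume values as described above.
    absolute_volume_cc:
        Optional structure volume in cc (metadata only).
    patient_id, course:
        Optional provenance labels used by the CSV round trip.
    """

    structure_name: str
    mode: str
    dose_edges: np.ndarray
    volume: np.ndarray
    absolute_volume_cc: float | None = None
    patient_id: str | None = None
    course: str | None = None

    def __post_init__(self):
        edges = np.asarray(self.dose_edges, dtype=float)
        vol = np.asarray(self.volume, dtype=float)
        object.__setattr__(self, "dose_edges", edges)
        object.__setattr__(self, "volume", vol)
        if self.mode not in (CUMULATIVE, DIFFERENTIAL):
            raise ValidationError(f"unknown DVH mode {self.mode!r}")
        if edges.ndim != 1 or edges.size < 2:
            raise ValidationError("dose_edges must be a 1-d array with >= 2 entries")
        if edges[0] < 0:
            raise ValidationError("dose_edges must be non-negative")
        diffs = np.diff(edges)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ValidationError(
                f"dose_edges must be strictly increasing (violation at index {i + 1})"
            )
        if self.mode == CUMULATIVE:
            if vol.shape != edges.shape:
                raise ValidationError(
                    "cumulative DVH needs one volume value per dose edge"
                )
            if abs(vol[0] - 1.0) > 1e-9:
                raise ValidationError(f"cumulative DVH must start at 1.0, got {vol[0]}")
            if np.any(vol < -1e-12) or np.any(vol > 1.0 + 1e-12):
                raise ValidationError("cumulative volume fractions must lie in [0, 1]")
            inc = np.diff(vol)
            if np.any(inc > 1e-9):
                i = int(np.argmax(inc > 1e-9))
                raise ValidationError(
                    f"cumulative DVH must be non-increasing (violation at index {i + 1})"
                )
        else:
            if vol.shape[0] != edges.shape[0] - 1:
                raise ValidationError(
                    "differential DVH needs exactly one value per dose bin"
                )
            if np.any(vol < -1e-12):
                i = int(np.argmax(vol < -1e-12))
                raise ValidationError(f"negative bin fraction at index {i}")
            if abs(vol.sum() - 1.0) > 1e-9:
                raise ValidationError(
                    f"differential DVH fractions must sum to 1, got {vol.sum()}"
                )

    @property
    def bin_midpoints(self) -> np.ndarray:
        """Representative dose of each bin (midpoint of adjacent edges)."""
        return 0.5 * (self.dose_edges[:-1] + self.dose_edges[1:])

    def with_labels(self, patient_id: str | None = None, course: str | None = None):
        return replace(self, patient_id=patient_id, course=course)


@dataclass(frozen=True)
class DoseSummary:
    """Near-minimum, mean and near-maximum dose of a structure, in Gy."""

    d_min: float
    d_mean: float
    d_max: float

    def __post_init__(self):
        if not (self.d_min <= self.d_mean + 1e-9 and self.d_mean <= self.d_max + 1e-9):
            raise ValidationError(
                f"dose summary must satisfy d_min <= d_mean <= d_max, "
                f"got ({self.d_min}, {self.d_mean}, {self.d_max})"
            )


def to_differential(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a cumulative DVH to differential form on the same edges.

    Bin ``i`` receives ``cumulative(edge_i) - cumulative(edge_{i+1})``; the
    representative dose of the bin is the edge midpoint.
    """
    if dvh.mode != CUMULATIVE:
        raise ValidationError("to_differential expects a cumulative DVH")
    fractions = -np.diff(dvh.volume)
    # residual volume beyond the last edge is zero by the cumulative contract
    # (the grid is expected to extend past the maximum dose); fold any leftover
    # into the last bin so fractions keep summing to volume[0]
    fractions = fractions.copy()
    fractions[-1] += dvh.volume[-1]
    return replace(dvh, mode=DIFFERENTIAL, volume=fractions)


def to_cumulative(dvh: DoseVolumeHistogram) -> DoseVolumeHistogram:
    """Convert a differential DVH back to cumulative form on the same edges.

    The cumulative value at edge ``j`` is the total fraction of bins at or
    above that edge, which inverts :func:`to_differential` exactly.
    """
    if dvh.mode != DIFFERENTIAL:
        raise ValidationError("to_cumulative expects a differential DVH")
    tail = np.concatenate([np.cumsum(dvh.volume[::-1])[::-1], [0.0]])
    # clean floating noise so the result passes the cumulative invariants
    tail = np.clip(tail, 0.0, 1.0)
    tail[0] = 1.0 if abs(tail[0] - 1.0) <= 1e-9 else tail[0]
    return replace(dvh, mode=CUMULATIVE, volume=tail)


def resample_cumulative(
    dvh: DoseVolumeHistogram, grid: Sequence[float]
) -> DoseVolumeHistogram:
    """Linearly interpolate a cumulative DVH onto a new dose grid.

    Doses beyond the original support map to volume 0.  The grid must be
    strictly increasing and start at 0 Gy.
    """
    if dvh.mode != CUMULATIVE:
        raise ValidationError("resample_cumulative expects a cumulative DVH")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValidationError("resampling grid is empty")
    if grid[0] != 0.0:
        raise ValidationError("resampling grid must start at 0 Gy")
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValidationError("resampling grid must be strictly increasing")
    values = np.interp(grid, dvh.dose_edges, dvh.volume)
    values[grid > dvh.dose_edges[-1]] = 0.0
    return replace(dvh, dose_edges=grid, volume=values)


def default_grid(max_dose_gy: float, bin_gy: float = DEFAULT_BIN_GY) -> np.ndarray:
    """Regular dose grid from 0 to one bin past ``max_dose_gy``."""
    n = int(np.ceil(max_dose_gy / bin_gy)) + 1
    return np.arange(n + 1) * bin_gy


def ingest_digitized_points(
    points: Iterable[tuple[float, float]],
    structure_name: str = "digitized",
) -> DoseVolumeHistogram:
    """Build a cumulative DVH from digitised (dose, volume-fraction) points.

    The points are sorted by dose, volume values are clipped to [0, 1], and
    monotonicity is restored with a running minimum (each value replaced by
    the minimum over all points at lower or equal dose) — the simplest
    order-preserving projection for jittery hand-digitised curves.  A point
    (0, 1.0) is prepended when the curve does not start at 0 Gy.
    """
    pts = [(float(d), float(v)) for d, v in points]
    if len(pts) < 2:
        raise ValidationError("need at least 2 digitized points")
    doses = np.array([p[0] for p in pts])
    if np.any(doses < 0):
        raise ValidationError("digitized doses must be non-negative")
    if np.all(doses == doses[0]):
        raise ValidationError("digitized points collapse onto a single dose")
    order = np.argsort(doses, kind="stable")
    doses = doses[order]
    vols = np.clip(np.array([p[1] for p in pts])[order], 0.0, 1.0)
    # average duplicated doses so edges stay strictly increasing
    uniq, inverse = np.unique(doses, return_inverse=True)
    if uniq.size != doses.size:
        vols = np.bincount(inverse, weights=vols) / np.bincount(inverse)
        doses = uniq
    vols = np.minimum.accumulate(vols)
    if doses[0] > 0:
        doses = np.concatenate([[0.0], doses])
        vols = np.concatenate([[1.0], vols])
    else:
        vols[0] = 1.0
        vols = np.minimum.accumulate(vols)
    return DoseVolumeHistogram(structure_name, CUMULATIVE, doses, vols)


def dose_summary(dvh: DoseVolumeHistogram) -> DoseSummary:
    """Near-min, mean and near-max dose of a DVH.

    The mean is the fraction-weighted sum of bin midpoints.  The
    near-extremes use a volume threshold of ``VOLUME_EPS``: ``d_max`` is the
    right edge of the highest bin holding more than that fraction, ``d_min``
    the left edge of the lowest such bin.
    """
    diff = to_differential(dvh) if dvh.mode == CUMULATIVE else dvh
    mids = diff.bin_midpoints
    occupied = np.flatnonzero(diff.volume > VOLUME_EPS)
    if occupied.size == 0:
        return DoseSummary(0.0, 0.0, 0.0)
    d_mean = float(np.dot(diff.volume, mids))
    d_min = float(diff.dose_edges[occupied[0]])
    d_max = float(diff.dose_edges[occupied[-1] + 1])
    return DoseSummary(d_min, d_mean, d_max)


def write_dvh_csv(dvhs: Sequence[DoseVolumeHistogram], path) -> None:
    """Write DVHs to the package CSV dialect.

    One row per dose edge.  For differential histograms the last edge has no
    bin of its own; its ``volume_fraction`` cell is left blank and ignored on
    read, which keeps the round trip lossless.
    """
    frames = []
    for dvh in dvhs:
        n_edges = dvh.dose_edges.size
        vol = dvh.volume
        if dvh.mode == DIFFERENTIAL:
            vol = np.concatenate([vol, [np.nan]])
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [dvh.patient_id or ""] * n_edges,
                    "course": [dvh.course or ""] * n_edges,
                    "structure": [dvh.structure_name] * n_edges,
                    "mode": [dvh.mode] * n_edges,
                    "dose_gy": np.round(dvh.dose_edges, 6),
                    "volume_fraction": np.round(vol, 6),
                    "absolute_volume_cc": [
                        "" if dvh.absolute_volume_cc is None else dvh.absolute_volume_cc
                    ]
                    * n_edges,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dvh_csv(path) -> list[DoseVolumeHistogram]:
    """Read DVHs from the package CSV dialect (inverse of write_dvh_csv)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in raw.columns]
    if missing:
        raise ParseError(f"missing required columns: {', '.join(missing)}", line=1)

    def _num(column: str, allow_blank: bool) -> np.ndarray:
        out = np.empty(len(raw))
        for i, cell in enumerate(raw[column]):
            if cell == "" and allow_blank:
                out[i] = np.nan
                continue
            try:
                out[i] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} in column {column}", line=i + 2
                ) from None
        return out

    dose = _num("dose_gy", allow_blank=False)
    vol = _num("volume_fraction", allow_blank=True)
    abs_vol = _num("absolute_volume_cc", allow_blank=True)

    bad_mode = ~raw["mode"].isin([CUMULATIVE, DIFFERENTIAL])
    if bad_mode.any():
        i = int(np.argmax(bad_mode.to_numpy()))
        raise ParseError(f"unknown mode token {raw['mode'].iloc[i]!r}", line=i + 2)

    dvhs = []
    keys = raw[["patient_id", "course", "structure", "mode"]].agg(tuple, axis=1)
    for (pid, course, structure, mode), idx in keys.groupby(keys, sort=False).groups.items():
        idx = np.asarray(idx)
        order = idx[np.argsort(dose[idx], kind="stable")]
        edges = dose[order]
        values = vol[order]
        if mode == DIFFERENTIAL:
            values = values[:-1]
        av = abs_vol[order][0]
        dvhs.append(
            DoseVolumeHistogram(
                structure_name=structure,
                mode=mode,
                dose_edges=edges,
                volume=values,
                absolute_volume_cc=None if np.isnan(av) else float(av),
                patient_id=pid or None,
                course=course or None,
            )
        )
    return dvhs
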