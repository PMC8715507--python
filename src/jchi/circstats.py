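"""Circular statistics for dihedral angles.

Angles are treated as directions on the circle: each value x is mapped to
the unit vector (cos x, sin x).  Distances are minor arcs in [0, 180]
degrees, means are computed with the four-quadrant arctangent, and
root-mean-square deviations between two angle sets use the circular
distance with an optional exclusion threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._angles import wrap_degrees
from .errors import DegenerateMeanError, InvalidInputError

__all__ = [
    "AngleSeries",
    "RobustAverageResult",
    "circ_distance",
    "circ_mean",
    "circ_rms_deviation",
    "rmsd_chi1",
    "robust_xray_average",
]


@dataclass(frozen=True)
class AngleSeries:
    """A set of dihedral angles (degrees) with optional per-value source
    labels (e.g. PDB entry ids).  Values are wrapped to (-180, 180] on
    construction."""

    values: tuple
    sources: tuple = ()

    def __init__(self, values: Sequence[float], sources: Sequence[str] | None = None):
        vals = tuple(float(wrap_degrees(v)) for v in values)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidInputError("angle values must be finite")
        srcs = tuple(sources) if sources is not None else tuple("" for _ in vals)
        if len(srcs) != len(vals):
            raise InvalidInputError("sources must match values in length")
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "sources", srcs)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class RobustAverageResult:
    """Outcome of outlier-robust circular averaging."""

    mean: float
    spread: float
    n_used: int
    excluded: tuple = field(default_factory=tuple)


def circ_distance(a: float, b: float) -> float:
    """Minor arc between two directions, in [0, 180] degrees."""
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidInputError("angles must be finite")
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def circ_mean(series: AngleSeries | Sequence[float]) -> float:
    """Circular mean: atan2 of the summed unit vectors, in degrees.

    Raises :class:`DegenerateMeanError` when the resultant vector is
    (numerically) zero, e.g. for an antipodal pair.
    """
    values = series.values if isinstance(series, AngleSeries) else tuple(series)
    if len(values) == 0:
        raise InvalidInputError("cannot average an empty angle series")
    rad = np.radians(np.asarray(values, dtype=float))
    x = float(np.sum(np.cos(rad)))
    y = float(np.sum(np.sin(rad)))
    if math.hypot(x, y) < 1e-9 * len(values):
        raise DegenerateMeanError(
            "circular mean undefined: resultant vector has zero length"
        )
    return wrap_degrees(math.degrees(math.atan2(y, x)))


def circ_rms_deviation(series: AngleSeries | Sequence[float], center: float) -> float:
    """Root-mean-square circular deviation of a series about *center*."""
    values = series.values if isinstance(series, AngleSeries) else tuple(series)
    devs = [circ_distance(v, center) for v in values]
    return float(np.sqrt(np.mean(np.square(devs))))


def rmsd_chi1(
    set1: Mapping[str, float],
    set2: Mapping[str, float],
    exclusion: float = 40.0,
) -> tuple[float, int, float]:
    """Circular rmsd between two residue->angle mappings.

    Residues present in both sets are compared with :func:`circ_distance`;
    pairs deviating strictly more than *exclusion* degrees are dropped.
    Returns ``(rmsd_degrees, n_used, max_deviation)`` where the maximum is
    taken over all shared residues (before exclusion).
    """
    shared = sorted(set(set1) & set(set2))
    if not shared:
        raise InvalidInputError("no residues shared between the two angle sets")
    devs = np.array([circ_distance(set1[r], set2[r]) for r in shared])
    kept = devs[devs <= exclusion]
    if kept.size == 0:
        raise InvalidInputError(
            f"no shared residues survive the {exclusion} degree exclusion"
        )
    return float(np.sqrt(np.mean(kept**2))), int(kept.size), float(devs.max())


def robust_xray_average(
    series: AngleSeries,
    threshold: float = 30.0,
    iterate: bool = True,
) -> RobustAverageResult:
    """Average a set of crystallographic angles, discarding outliers.

    Repeats { mean of retained values; drop values deviating more than
    *threshold* from that mean } until the retained set is stable (or once,
    with ``iterate=False``).  The retained set can only shrink, so at most
    ``len(series)`` passes run.
    """
    if len(series) == 0:
        raise InvalidInputError("cannot average an empty angle series")
    retained = list(range(len(series)))
    mean = circ_mean([series.values[i] for i in retained])
    for _ in range(len(series)):
        keep = [i for i in retained if circ_distance(series.values[i], mean) <= threshold]
        if not keep:
            raise InvalidInputError(
                "all values excluded as outliers; threshold too tight"
            )
        changed = keep != retained
        retained = keep
        mean = circ_mean([series.values[i] for i in retained])
        if not changed or not iterate:
            break
    excluded = tuple(
        (series.values[i], series.sources[i])
        for i in range(len(series))
        if i not in retained
    )
    spread = circ_rms_deviation([series.values[i] for i in retained], mean)
    return RobustAverageResult(
        mean=mean, spread=spread, n_used=len(retained), excluded=excluded
    )
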