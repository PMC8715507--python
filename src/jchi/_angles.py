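"""Shared angle helpers.  All public angles in the package are degrees
wrapped to the half-open interval (-180, 180]."""

from __future__ import annotations

import numpy as np


def wrap_degrees(angle):
    """Wrap an angle (scalar or array, degrees) to (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    w = -(np.mod(-a + 180.0, 360.0) - 180.0)
    if w.ndim == 0:
        return float(w)
    return w


STAGGERED_ANGLES = (60.0, 180.0, -60.0)


def nearest_staggered(angle: float) -> float:
    """Return the staggered angle (60, 180 or -60) closest to *angle*
    on the circle."""
    from .circstats import circ_distance

    return min(STAGGERED_ANGLES, key=lambda s: circ_distance(angle, s))
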