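"""Wrap-aware arithmetic for backbone dihedral angles on the torus S1 x S1.

Backbone torsion angles (phi, psi) live on a torus: each angle wraps around
at +/-180 degrees.  Plain Euclidean averages and distances are therefore
wrong near the seam, and every downstream computation (angle aggregation
across crystal structures, kernel placement in the density estimator) goes
through the functions here instead.

Angles are kept in degrees throughout, on the canonical interval
(-180, 180]; radians appear only inside trigonometric calls.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateMeanError",
    "wrap_angle",
    "torus_mean",
    "torus_distance",
    "arc_distance",
]


class DegenerateMeanError(ValueError):
    """Circular mean is undefined: the resultant vector has length ~0.

    Happens for perfectly antipodal configurations, e.g. {0, 180}.  Callers
    are expected to skip such positions rather than pick an arbitrary angle.
    """


def wrap_angle(theta):
    """Wrap an angle (or array of angles) in degrees onto (-180, 180].

    The upper end is closed so that e.g. -180 maps to 180.  Input must be
    finite.
    """
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("wrap_angle requires finite input")
    # 180 - ((180 - theta) mod 360) lands exactly on (-180, 180]
    wrapped = 180.0 - np.mod(180.0 - theta, 360.0)
    if wrapped.ndim == 0:
        return float(wrapped)
    return wrapped


def torus_mean(points, *, tol: float = 1e-12):
    """Per-component circular mean of (phi, psi) pairs.

    The centroid on the torus is approximated component-wise via
    atan2(sum sin, sum cos).  ``points`` is an (N, 2) array-like of
    canonical (phi, psi) pairs in degrees; the result is a canonical pair.

    Raises
    ------
    ValueError
        on an empty point set.
    DegenerateMeanError
        if either component's resultant length is ~0 (antipodal degeneracy),
        relative to the number of points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("torus_mean of an empty point set is undefined")
    if pts.shape[1] != 2:
        raise ValueError("expected (N, 2) array of (phi, psi) pairs")
    rad = np.radians(pts)
    s = np.sin(rad).sum(axis=0)
    c = np.cos(rad).sum(axis=0)
    resultant = np.hypot(s, c)
    if np.any(resultant < tol * max(1, len(pts))):
        raise DegenerateMeanError(
            "circular mean undefined: zero resultant in at least one component"
        )
    mean = np.degrees(np.arctan2(s, c))
    return float(wrap_angle(mean[0])), float(wrap_angle(mean[1]))


def arc_distance(delta):
    """Shortest arc length in degrees for an angle difference.

    Computes arccos(cos(delta)) elementwise, mapping any difference to
    [0, 180]; this is the wrap-around distance on the circle.
    """
    delta = np.mod(np.asarray(delta, dtype=float), 360.0)
    c = np.clip(np.cos(np.radians(delta)), -1.0, 1.0)
    out = np.degrees(np.arccos(c))
    if out.ndim == 0:
        return float(out)
    return out


def torus_distance(p1, p2):
    """Distance in degrees between two points on the torus.

    sqrt(arc(phi1 - phi2)^2 + arc(psi1 - psi2)^2) where arc is the
    wrap-around circle distance in [0, 180].
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = arc_distance(p1 - p2)
    return float(np.sqrt(np.sum(np.square(d), axis=-1)))
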