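"""Helix-axis estimation from Calpha coordinates.

For a point orbit of a screw motion (an ideal helix), the bisector vector
``p[i-1] + p[i+1] - 2 p[i]`` is exactly radial, so cross products of
successive bisectors are exactly axial.  Averaging those cross products
therefore recovers the screw axis to machine precision on ideal helices and
degrades gracefully on real ones — unlike the principal axis of a short
window's Calpha cloud, which is biased by several degrees whenever the
window does not span a whole number of turns.
"""

from __future__ import annotations

import numpy as np

from .errors import InsufficientDataError


def helix_axis(ca_coords: np.ndarray) -> np.ndarray:
    """Unit helix-axis estimate from ordered Calpha coordinates (>= 4 points).

    The sign convention is inherited from the point ordering: the returned
    axis points from the first toward the last coordinate.
    """
    p = np.asarray(ca_coords, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) < 4:
        raise InsufficientDataError("helix axis needs >= 4 ordered CA coordinates")
    radial = p[:-2] + p[2:] - 2 * p[1:-1]
    norms = np.linalg.norm(radial, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise InsufficientDataError("collinear CA run; no helical curvature")
    radial = radial / norms
    crosses = np.cross(radial[:-1], radial[1:])
    cnorms = np.linalg.norm(crosses, axis=1, keepdims=True)
    if np.all(cnorms < 1e-12):
        raise InsufficientDataError("degenerate CA geometry; axis undetermined")
    crosses = crosses / np.where(cnorms < 1e-12, 1.0, cnorms)
    m = crosses.mean(axis=0)
    n = np.linalg.norm(m)
    if n < 1e-12:
        raise InsufficientDataError("bisector crosses cancel; axis undetermined")
    axis = m / n
    if np.dot(axis, p[-1] - p[0]) < 0:
        axis = -axis
    return axis
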