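"""Internal-coordinate geometry: torsion measurement and NeRF atom placement."""

from __future__ import annotations

import numpy as np

__all__ = ["normalize_angle", "measure_dihedral", "place_atom"]

_COLLINEAR_TOL = 1e-8


def normalize_angle(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    a = (float(deg) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, IUPAC convention.

    Looking from p2 towards p3, a clockwise rotation of p4 relative to
    p1 is positive.  Result lies in (-180, 180].  Raises on collinear
    triples, for which the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _COLLINEAR_TOL or np.linalg.norm(n2) < _COLLINEAR_TOL:
        raise ValueError("torsion undefined: three of the four points are collinear")
    b2u = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, b2u), n2))
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to C using internal coordinates (NeRF).

    Parameters
    ----------
    a, b, c
        Reference coordinates; D is placed such that |C-D| = ``bond``,
        the B-C-D angle equals ``angle`` (degrees) and the A-B-C-D
        torsion equals ``torsion`` (degrees).
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _COLLINEAR_TOL:
        raise ValueError("cannot place atom: reference points are collinear")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            -bond * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
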