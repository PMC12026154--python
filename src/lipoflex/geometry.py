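"""Small vector-geometry helpers shared by the hydrogen builder, the point
mutator, the synthetic-structure generator and the trajectory metrics."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a zero-length vector")
    return v / n


def rotation_about(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix about *axis* by *theta* radians (Rodrigues)."""
    k = unit(np.asarray(axis, dtype=float))
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def place_internal(c: np.ndarray, b: np.ndarray, a: np.ndarray,
                   bond: float, angle: float, dihedral: float) -> np.ndarray:
    """Position of atom D bonded to *c* with |D-c| = bond, angle(D,c,b) =
    *angle* and dihedral(D,c,b,a) = *dihedral* (angles in radians).

    Standard natural-extension-reference-frame construction used to grow
    chains from internal coordinates.
    """
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.stack([bc, np.cross(n, bc), n])
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d @ m


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle (radians) of four points."""
    b0 = p1 - p0
    b1 = unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    return float(np.arctan2(np.dot(np.cross(b1, v), w), np.dot(v, w)))


def kabsch(mobile: np.ndarray, ref: np.ndarray,
           weights: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Weighted least-squares rigid superposition of *mobile* onto *ref*.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits *ref*,
    with ``det(R) = +1`` (proper rotation).  Requires at least three
    non-collinear points.
    """
    mobile = np.asarray(mobile, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3) and congruent")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    mc = (w[:, None] * mobile).sum(axis=0)
    rc = (w[:, None] * ref).sum(axis=0)
    X = mobile - mc
    Y = ref - rc
    # collinearity check on the reference
    if np.linalg.matrix_rank(Y - Y.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    H = (w[:, None] * X).T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = X @ R.T + rc
    rmsd = float(np.sqrt((w * ((fitted - ref) ** 2).sum(axis=1)).sum()))
    return R, t, rmsd


def superpose(mobile: np.ndarray, ref: np.ndarray,
              weights: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Apply the optimal rigid transform; returns (fitted coords, rmsd)."""
    R, t, rmsd = kabsch(mobile, ref, weights)
    return mobile @ R.T + t, rmsd
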