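"""Solvent-accessible surface area by the Shrake-Rupley method.

A deterministic golden-spiral point lattice is rolled over the van der Waals
spheres (probe 1.4 A, 256 points by default).  The lattice is expressed in a
molecule-fixed frame derived from the coordinate inertia tensor (with a
skewness-based sign convention), so the computed areas are invariant under
rigid motion of the whole molecule rather than tied to the laboratory axes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from . import templates as T
from .structure import StructureModel


def sphere_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere lattice (golden spiral)."""
    if n < 1:
        raise ValueError("need at least one sphere point")
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def molecule_frame(coords: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame (rows) fixed in the molecule.

    Axes are the principal axes of the centred coordinates ordered by
    decreasing variance; each of the first two axes is oriented so the
    coordinate skewness along it is non-negative (a rotation-equivariant sign
    rule), and the third completes the right-handed set.  For degenerate or
    skewness-free point sets the frame falls back to a fixed convention, in
    which case exact rigid-motion invariance is not guaranteed.
    """
    c = coords - coords.mean(axis=0)
    if len(c) < 3:
        return np.eye(3)
    cov = c.T @ c
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    axes = v[:, order].T  # rows
    for k in range(2):
        s = np.sum((c @ axes[k]) ** 3)
        if abs(s) > 1e-8:
            axes[k] = axes[k] * np.sign(s)
        else:
            j = int(np.argmax(np.abs(axes[k])))
            axes[k] = axes[k] * np.sign(axes[k][j] or 1.0)
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def atom_radii(model: StructureModel) -> np.ndarray:
    radii = np.empty(len(model))
    for i, a in enumerate(model.atoms):
        try:
            radii[i] = T.VDW_RADII[a.element]
        except KeyError:
            raise ValueError(f"no van der Waals radius for element {a.element!r} "
                             f"(atom {a.name} in {a.chain}:{a.res_seq})") from None
    return radii


def shrake_rupley(coords: np.ndarray, radii: np.ndarray, *,
                  probe_radius: float = 1.4, n_points: int = 256) -> np.ndarray:
    """Per-atom solvent-accessible surface areas (A^2)."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    if radii.shape != (n,):
        raise ValueError("radii incongruent with coordinates")
    lattice = sphere_points(n_points) @ molecule_frame(coords)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    max_ext = ext.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + ext[i] * lattice
        nbrs = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                if j != i]
        if nbrs:
            d2 = ((pts[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[nbrs] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas


def compute_sasa(model: StructureModel, *, probe_radius: float = 1.4,
                 n_points: int = 256) -> np.ndarray:
    """Per-atom SASA of a structure using the spec'd van der Waals radii
    (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 A)."""
    return shrake_rupley(model.coords, atom_radii(model),
                         probe_radius=probe_radius, n_points=n_points)
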