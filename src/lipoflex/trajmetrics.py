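"""Trajectory-derived structural observables.

Superposition (Kabsch), RMSD and per-residue RMSF, radius of gyration,
SASA time series, helix-barrel interface distance (D_max / D_ave +/- SD)
and essential-dynamics PCA of the Calpha coordinate covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import templates as T
from .geometry import kabsch, superpose
from .sasa import atom_radii, shrake_rupley
from .structure import StructureModel, Trajectory

kabsch_superpose = kabsch  # the module-level name for the superposition op


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (A), keyed by (chain, res_seq)."""

    rmsf: dict[tuple[str, int], float]
    selection: str = "CA"
    res_names: dict[tuple[str, int], str] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.rmsf.values()):
            raise ValueError("negative RMSF")


@dataclass
class HelixBarrelSeries:
    d: np.ndarray
    pair_spec: list[tuple[tuple[str, int], tuple[str, int]]]
    aggregator: str = "mean-over-pairs"

    @property
    def D_max(self) -> float:
        return float(np.max(self.d))

    @property
    def D_ave(self) -> float:
        return float(np.mean(self.d))

    @property
    def D_sd(self) -> float:
        return float(np.std(self.d, ddof=1)) if len(self.d) > 1 else 0.0


@dataclass
class PCAResult:
    eigenvalues: np.ndarray          # descending, A^2 (or nm^2)
    eigenvectors: np.ndarray         # columns, 3N-dim
    projections: np.ndarray          # (n_frames, n_components)
    ranges: list[tuple[float, float]]
    explained_variance: np.ndarray   # fractions of total variance
    units: str = "angstrom"


def _superposed_frames(traj: Trajectory, idx: np.ndarray,
                       ref: np.ndarray) -> np.ndarray:
    out = np.empty((traj.n_frames, len(idx), 3))
    for f in range(traj.n_frames):
        out[f], _ = superpose(traj.frames[f][idx], ref)
    return out


def rmsd_series(traj: Trajectory, ref_frame: int = 0,
                selection: str | None = "CA") -> np.ndarray:
    """Per-frame RMSD (A) after optimal superposition on a reference frame."""
    idx = traj.atom_indices(selection)
    ref = traj.frames[ref_frame][idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, out[f] = superpose(traj.frames[f][idx], ref)
    return out


def rmsf_profile(traj: Trajectory, selection: str = "CA",
                 fit: bool = True) -> FlexibilityProfile:
    """Per-residue RMSF about the time-average position.

    With ``fit=True`` frames are first superposed on the time-average
    structure (one refinement pass, as MD tooling conventionally does).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least two frames")
    idx = traj.atom_indices(selection)
    X = traj.frames[:, idx, :]
    if fit:
        mean = X.mean(axis=0)
        X = _superposed_frames(traj, idx, mean)
        mean = X.mean(axis=0)
        for f in range(X.shape[0]):
            X[f], _ = superpose(X[f], mean)
    mean = X.mean(axis=0)
    msf = ((X - mean) ** 2).sum(axis=2).mean(axis=0)
    rmsf = np.sqrt(msf)
    prof: dict[tuple[str, int], float] = {}
    names: dict[tuple[str, int], str] = {}
    for k, i in enumerate(idx):
        atom = traj.reference.atoms[i]
        prof[atom.residue_key] = float(rmsf[k])
        names[atom.residue_key] = atom.res_name
    return FlexibilityProfile(rmsf=prof, selection=selection, res_names=names)


def gyration_series(traj: Trajectory, mass_weighted: bool = True) -> np.ndarray:
    """Radius of gyration (A) per frame, mass-weighted by default."""
    if mass_weighted:
        w = np.array([T.ATOMIC_MASSES.get(a.element, 12.011)
                      for a in traj.reference.atoms])
    else:
        w = np.ones(len(traj.reference))
    w = w / w.sum()
    com = (traj.frames * w[None, :, None]).sum(axis=1, keepdims=True)
    sq = ((traj.frames - com) ** 2).sum(axis=2)
    return np.sqrt((sq * w[None, :]).sum(axis=1))


def sasa_series(traj: Trajectory, selection=None, *, probe_radius: float = 1.4,
                n_points: int = 256, stride: int = 1) -> np.ndarray:
    """Per-frame SASA (A^2) of a selection, computed in the whole-protein
    context (Shrake-Rupley on every stride-th frame).

    ``selection`` may be None (total), an atom-name string, a (chain,
    res_seq) residue key, or an explicit index array.
    """
    model = traj.reference
    radii = atom_radii(model)
    if selection is None:
        idx = np.arange(len(model))
    elif isinstance(selection, str):
        idx = traj.atom_indices(selection)
    elif isinstance(selection, tuple) and len(selection) == 2 \
            and isinstance(selection[0], str):
        idx = np.array(model.residue_atom_indices(*selection))
    else:
        idx = np.asarray(selection, dtype=int)
    out = []
    for f in range(0, traj.n_frames, stride):
        areas = shrake_rupley(traj.frames[f], radii,
                              probe_radius=probe_radius, n_points=n_points)
        out.append(areas[idx].sum())
    return np.array(out)


def helix_barrel_distance(traj: Trajectory,
                          pair_spec: list[tuple[tuple[str, int], tuple[str, int]]],
                          aggregator: str = "mean-over-pairs") -> HelixBarrelSeries:
    """Helix-to-barrel interface distance series from Calpha pairs.

    ``pair_spec`` lists (helix residue, barrel residue) keys; the per-frame
    distance is the aggregator (default mean) over the listed Calpha pairs.
    """
    if not pair_spec:
        raise ValueError("pair_spec must list at least one residue pair")
    if aggregator not in ("mean-over-pairs", "min-over-pairs"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    model = traj.reference
    idx_pairs = []
    for (h, b) in pair_spec:
        try:
            hi = model.atom_index(h[0], h[1], "CA")
            bi = model.atom_index(b[0], b[1], "CA")
        except KeyError as exc:
            raise KeyError(f"helix-barrel pair {h}-{b}: {exc}") from None
        idx_pairs.append((hi, bi))
    hi = np.array([p[0] for p in idx_pairs])
    bi = np.array([p[1] for p in idx_pairs])
    d_pairs = np.linalg.norm(traj.frames[:, hi, :] - traj.frames[:, bi, :], axis=2)
    agg = d_pairs.mean(axis=1) if aggregator == "mean-over-pairs" else d_pairs.min(axis=1)
    return HelixBarrelSeries(d=agg, pair_spec=list(pair_spec), aggregator=aggregator)


def pca_essential(traj: Trajectory, selection: str | None = "CA",
                  n_components: int = 2, units: str = "angstrom") -> PCAResult:
    """Essential-dynamics PCA of the coordinate covariance.

    Frames are superposed on the time-average structure, the 3N-dimensional
    covariance is eigendecomposed, and each frame is projected on the leading
    components (PC1, PC2, ...).  ``units="nm"`` rescales projections and
    eigenvalues for comparison with nm-reported essential subspaces.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least two frames")
    scale = 0.1 if units == "nm" else 1.0
    if units not in ("angstrom", "nm"):
        raise ValueError(f"unknown units {units!r}")
    idx = traj.atom_indices(selection)
    X = traj.frames[:, idx, :]
    mean = X.mean(axis=0)
    X = _superposed_frames(traj, idx, mean)
    mean = X.mean(axis=0)
    flat = (X - mean).reshape(traj.n_frames, -1) * scale
    n_components = min(n_components, flat.shape[1], traj.n_frames)
    U, s, Vt = np.linalg.svd(flat, full_matrices=False)
    eigvals = s ** 2 / (traj.n_frames - 1)
    total_var = float(eigvals.sum())
    proj = flat @ Vt[:n_components].T
    ranges = [(float(proj[:, k].min()), float(proj[:, k].max()))
              for k in range(n_components)]
    explained = eigvals[:n_components] / total_var if total_var > 0 \
        else np.zeros(n_components)
    return PCAResult(eigenvalues=eigvals[:n_components],
                     eigenvectors=Vt[:n_components].T,
                     projections=proj, ranges=ranges,
                     explained_variance=explained, units=units)


def nearest_helix_pairing(model: StructureModel,
                          helix_residues: list[tuple[str, int]],
                          barrel_residues: list[tuple[str, int]],
                          ) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Default interface pairing: each barrel residue paired with its nearest
    helix Calpha in the reference structure (a replication choice; the pair
    list itself can always be supplied explicitly instead)."""
    coords = model.coords
    h_idx = {h: model.atom_index(h[0], h[1], "CA") for h in helix_residues}
    pairs = []
    for b in barrel_residues:
        bi = model.atom_index(b[0], b[1], "CA")
        best = min(helix_residues,
                   key=lambda h: np.linalg.norm(coords[h_idx[h]] - coords[bi]))
        pairs.append((best, b))
    return pairs
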