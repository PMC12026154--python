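"""Synthetic structures and trajectories with known ground truth.

The toy protein emulates the lipocalin topology at reduced scale: strands of
an antiparallel barrel-like body traced on a cylinder, with an adjacent
ideal alpha-helical segment resting at a prescribed distance from the wall.
Two trajectory generators supply exact ground truth for the trajectory
metrics: per-residue isotropic harmonic fluctuation (RMSF recovery) and a
collective "breathing" mode that modulates the helix-body distance as
d0 + A*sin(2*pi*t/period) exactly, by construction.

Peptide backbones are grown from ideal internal coordinates (NeRF); side
chains are grafted from the chemical component dictionary's ideal residue
geometries, so the hydropathy stages run on generated structures unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.spatial import cKDTree
import biotite.structure.info as _binfo

from . import templates as T
from .geometry import kabsch, place_internal, rotation_about, unit
from .structure import Atom, StructureModel, Trajectory

# ideal backbone internal coordinates (lengths A, angles degrees)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_A = {"N-CA-C": 111.0, "CA-C-N": 116.6, "C-N-CA": 121.7, "CA-C-O": 120.5}

CONFORMATIONS = {
    "extended": (-139.0, 135.0),   # antiparallel beta strand
    "helix": (-57.0, -47.0),       # ideal alpha helix (rise 1.5 A, 100 deg/res)
}

MIN_CLASH_DISTANCE = 1.0  # A

# rotation of the helical segment about its own axis; chosen once so the
# default fold packs the helix against the body without steric clashes
_HELIX_PHASE = np.radians(310.0)


@dataclass(frozen=True)
class ToySpec:
    """Geometry of the toy barrel-plus-helix fold."""

    n_strand_res: int = 8
    n_strands: int = 8
    n_helix_res: int = 10
    barrel_radius: float = 8.0     # A, cylinder radius of the strand traces
    helix_offset: float = 4.25     # A, resting helix-to-body distance d0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_strand_res, self.n_strands, self.n_helix_res) < 1:
            raise ValueError("all residue/strand counts must be >= 1")
        if self.barrel_radius <= 0 or self.helix_offset <= 0:
            raise ValueError("barrel_radius and helix_offset must be positive")


@dataclass(frozen=True)
class MotionSpec:
    """Ground-truth motion parameters for the trajectory generators."""

    sigmas: np.ndarray | float = 0.5    # A, per-residue per-coordinate SD
    breathing_amplitude: float = 1.65   # A
    breathing_period: int = 100         # frames
    n_frames: int = 500
    jitter: float = 0.02                # A, per-atom noise in the breathing mode
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if np.any(np.asarray(self.sigmas) < 0) or self.jitter < 0:
            raise ValueError("noise amplitudes must be non-negative")
        if self.breathing_period < 1:
            raise ValueError("breathing_period must be >= 1 frame")

    def sigma_vector(self, n_residues: int) -> np.ndarray:
        s = np.asarray(self.sigmas, dtype=float)
        if s.ndim == 0:
            return np.full(n_residues, float(s))
        if s.shape != (n_residues,):
            raise ValueError(f"sigma vector length {s.shape} does not match "
                             f"residue count {n_residues}")
        return s


# --------------------------------------------------------------------------
# backbone + side chain construction

def _backbone_chain(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Grow an ideal poly-peptide backbone with fixed (phi, psi), omega=180."""
    rphi, rpsi = np.radians(phi), np.radians(psi)
    res: list[dict[str, np.ndarray]] = []
    n = np.zeros(3)
    ca = np.array([_B["N-CA"], 0.0, 0.0])
    ang = np.radians(_A["N-CA-C"])
    c = ca + _B["CA-C"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    res.append({"N": n, "CA": ca, "C": c})
    for _ in range(1, n_res):
        prev = res[-1]
        n = place_internal(prev["C"], prev["CA"], prev["N"],
                           _B["C-N"], np.radians(_A["CA-C-N"]), rpsi)
        ca = place_internal(n, prev["C"], prev["CA"],
                            _B["N-CA"], np.radians(_A["C-N-CA"]), np.pi)
        c = place_internal(ca, n, prev["C"],
                           _B["CA-C"], np.radians(_A["N-CA-C"]), rphi)
        res.append({"N": n, "CA": ca, "C": c})
    # carbonyl oxygens: anti to the next amide nitrogen
    for i, r in enumerate(res):
        r["O"] = place_internal(r["C"], r["CA"], r["N"], _B["C-O"],
                                np.radians(_A["CA-C-O"]), rpsi - np.pi)
    return res


def _ideal_sidechain(res_name: str) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Ideal heavy side-chain geometry from the component dictionary:
    (backbone N/CA/C coords, side-chain atom names, side-chain coords)."""
    tpl = _binfo.residue(res_name)
    tpl = tpl[tpl.element != "H"]
    names = list(tpl.atom_name)
    frame = np.array([tpl.coord[names.index(x)] for x in ("N", "CA", "C")])
    wanted = sorted(T.sidechain_atom_names(res_name))
    sc_names = [n for n in names if n in wanted]
    sc_coords = np.array([tpl.coord[names.index(n)] for n in sc_names])
    return frame, sc_names, sc_coords


def _graft_sidechain(backbone: dict[str, np.ndarray], res_name: str,
                     only: set[str] | None = None) -> list[tuple[str, np.ndarray]]:
    if res_name == "GLY":
        return []
    frame, sc_names, sc_coords = _ideal_sidechain(res_name)
    target = np.array([backbone["N"], backbone["CA"], backbone["C"]])
    R, t, _ = kabsch(frame, target)
    placed = sc_coords @ R.T + t
    out = []
    for name, pos in zip(sc_names, placed):
        if only is None or name in only:
            out.append((name, pos))
    return out


def make_peptide(sequence: str, conformation: str = "extended",
                 chain: str = "A", start_seq: int = 1,
                 full_sidechains: bool = True) -> StructureModel:
    """Build an ideal-geometry peptide from a one-letter sequence."""
    if conformation not in CONFORMATIONS:
        raise ValueError(f"unknown conformation {conformation!r}")
    phi, psi = CONFORMATIONS[conformation]
    bb = _backbone_chain(len(sequence), phi, psi)
    # C-terminal carboxylate oxygen, in plane opposite the carbonyl O
    last = bb[-1]
    last["OXT"] = place_internal(last["C"], last["CA"], last["N"], 1.25,
                                 np.radians(117.0), np.radians(psi))
    atoms: list[Atom] = []
    serial = 1
    for i, code in enumerate(sequence):
        res_name = T.ONE_TO_THREE[code.upper()]
        res_seq = start_seq + i
        entries = [(n, bb[i][n]) for n in ("N", "CA", "C", "O")]
        if i == len(sequence) - 1:
            entries.append(("OXT", bb[i]["OXT"]))
        entries += _graft_sidechain(bb[i], res_name,
                                    only=None if full_sidechains else {"CB"})
        for name, pos in entries:
            atoms.append(Atom(serial=serial, name=name,
                              element=T.element_of(res_name, name),
                              res_name=res_name, res_seq=res_seq,
                              chain=chain, coords=pos))
            serial += 1
    return StructureModel(atoms)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    """Dominant axis of a point trace, oriented first-to-last."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    axis = vt[0]
    if np.dot(axis, points[-1] - points[0]) < 0:
        axis = -axis
    return axis


def _align_axis(axis: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix taking *axis* onto *target* (both unit vectors)."""
    a, b = unit(axis), unit(target)
    c = float(np.clip(np.dot(a, b), -1.0, 1.0))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 degree flip about any perpendicular
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_about(perp, np.pi)
    return rotation_about(np.cross(a, b), np.arccos(c))


def _segment_residues(names: list[str], conformation: str,
                      chain: str, start_seq: int) -> StructureModel:
    seq = "".join(T.THREE_TO_ONE[n] for n in names)
    return make_peptide(seq, conformation, chain=chain, start_seq=start_seq,
                        full_sidechains=False)


def make_toy_protein(spec: ToySpec = ToySpec()) -> StructureModel:
    """Build the toy barrel-plus-helix fold.

    Strand Calpha traces run antiparallel on a cylinder of the given radius;
    the helical segment is placed facing strand 0 with its Calpha centroid
    at ``helix_offset`` from strand 0's Calpha centroid.  Residues are
    poly-Leu with Ala at each segment end (side chains truncated at CB so
    fluctuation ground truth stays residue-exact).  Raises on steric
    clashes closer than 1 A.
    """
    atoms: list[Atom] = []
    res_seq = 1
    serial = 1
    segments: dict[str, list[tuple[str, int]]] = {"helix": [], "barrel": [],
                                                  "interface": []}

    def _names(n: int) -> list[str]:
        out = ["LEU"] * n
        out[0] = "ALA"
        if n > 1:
            out[-1] = "ALA"
        return out

    def _append(model: StructureModel, R: np.ndarray, shift: np.ndarray,
                seg_keys: list[str]) -> None:
        nonlocal res_seq, serial
        ca_idx = [i for i, a in enumerate(model.atoms) if a.name == "CA"]
        coords = model.coords @ R.T
        centroid = coords[ca_idx].mean(axis=0)
        coords = coords - centroid + shift
        seq_map: dict[int, int] = {}
        for a, pos in zip(model.atoms, coords):
            if a.res_seq not in seq_map:
                seq_map[a.res_seq] = res_seq
                for key in seg_keys:
                    segments[key].append(("A", res_seq))
                res_seq += 1
            atoms.append(Atom(serial=serial, name=a.name, element=a.element,
                              res_name=a.res_name, res_seq=seq_map[a.res_seq],
                              chain="A", coords=pos))
            serial += 1

    for s in range(spec.n_strands):
        seg = _segment_residues(_names(spec.n_strand_res), "extended", "A", 1)
        ca = np.array([a.coords for a in seg.atoms if a.name == "CA"])
        direction = np.array([0.0, 0.0, 1.0 if s % 2 == 0 else -1.0])
        R = _align_axis(_principal_axis(ca), direction) if len(ca) > 1 else np.eye(3)
        theta = 2 * np.pi * s / spec.n_strands
        shift = spec.barrel_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        keys = ["barrel"] + (["interface"] if s == 0 else [])
        _append(seg, R, shift, keys)

    helix = _segment_residues(_names(spec.n_helix_res), "helix", "A", 1)
    ca = np.array([a.coords for a in helix.atoms if a.name == "CA"])
    R = _align_axis(_principal_axis(ca), np.array([0.0, 0.0, 1.0]))
    R = rotation_about(np.array([0.0, 0.0, 1.0]), _HELIX_PHASE) @ R
    shift = (spec.barrel_radius + spec.helix_offset) * np.array([1.0, 0.0, 0.0])
    _append(helix, R, shift, ["helix"])

    model = StructureModel(atoms)
    model.segments = segments
    model.meta = {"helix_offset": spec.helix_offset,
                  "barrel_radius": spec.barrel_radius,
                  "normal": [1.0, 0.0, 0.0],
                  "toy_spec": spec}
    coords = model.coords
    tree = cKDTree(coords)
    close = tree.query_pairs(MIN_CLASH_DISTANCE)
    bonded = set(model.covalent_bonds)
    clashes = [p for p in close if p not in bonded]
    if clashes:
        i, j = sorted(clashes)[0]
        raise ValueError(f"geometry clash: atoms {i} and {j} closer than "
                         f"{MIN_CLASH_DISTANCE} A")
    model.validate()
    return model


# --------------------------------------------------------------------------
# trajectory generators

def make_harmonic_trajectory(model: StructureModel, motion: MotionSpec,
                             dt: float = 1.0) -> Trajectory:
    """Per-residue iid Gaussian displacement about the reference.

    Every atom of a residue moves together, so the per-residue positional
    variance is exactly 3*sigma^2 and RMSF ground truth is sigma*sqrt(3).
    """
    sigmas = motion.sigma_vector(len(model.residues))
    rng = np.random.default_rng(motion.seed)
    res_index = {(c, s): k for k, (c, s, _) in enumerate(model.residues)}
    atom_res = np.array([res_index[a.residue_key] for a in model.atoms])
    ref = model.coords
    disp = rng.normal(size=(motion.n_frames, len(model.residues), 3)) \
        * sigmas[None, :, None]
    frames = ref[None, :, :] + disp[:, atom_res, :]
    return Trajectory(reference=model, frames=frames, dt=dt)


@dataclass
class BreathingResult:
    trajectory: Trajectory
    pair_spec: list[tuple[tuple[str, int], tuple[str, int]]]
    d0: float
    amplitude: float
    period: int


def _matched_pairs(model: StructureModel, normal: np.ndarray,
                   max_perp: float = 2.0):
    """Helix/barrel Calpha pairs that track the breathing mode: for each
    helix residue, the interface Calpha with the smallest offset
    perpendicular to the breathing normal; pairs with more than *max_perp*
    of perpendicular offset are dropped (they dilute the mode signal)."""
    helix = model.segments.get("helix")
    barrel = model.segments.get("interface") or model.segments.get("barrel")
    if not helix or not barrel:
        raise ValueError("model has no identifiable helix segment; build it "
                         "with make_toy_protein")
    coords = model.coords
    pairs = []
    for h in helix:
        hc = coords[model.atom_index(h[0], h[1], "CA")]
        best, best_perp = None, np.inf
        for b in barrel:
            rel = hc - coords[model.atom_index(b[0], b[1], "CA")]
            perp = float(np.linalg.norm(rel - np.dot(rel, normal) * normal))
            if perp < best_perp:
                best, best_perp = b, perp
        if best_perp <= max_perp:
            pairs.append((h, best))
    if not pairs:
        raise ValueError("no helix/barrel pair tracks the breathing normal; "
                         "supply pair_spec explicitly")
    return pairs


def make_breathing_trajectory(model: StructureModel, motion: MotionSpec,
                              d0: float | None = None,
                              pair_spec=None, dt: float = 1.0) -> BreathingResult:
    """Collective helix-breathing trajectory with exact distance ground truth.

    The helix is rigid-body displaced along the barrel normal; the per-frame
    displacement magnitude is solved so that the mean Calpha distance over
    the matched pairs equals d0 + A*sin(2*pi*t/period) exactly, after which
    optional small Gaussian jitter is added to every atom.  Ground truth for
    the matched pair list: D_ave -> d0, D_max -> d0 + A.
    """
    normal0 = unit(np.asarray(model.meta.get("normal", [1.0, 0.0, 0.0]), float))
    if pair_spec is None:
        pair_spec = _matched_pairs(model, normal0)
    if d0 is None:
        d0 = float(model.meta.get("helix_offset", 0.0)) or None
    if d0 is None:
        raise ValueError("d0 not given and not recorded on the model")
    normal = unit(np.asarray(model.meta.get("normal", [1.0, 0.0, 0.0]), float))
    helix_res = set(model.segments["helix"])
    helix_mask = np.array([a.residue_key in helix_res for a in model.atoms])

    h_idx = np.array([model.atom_index(h[0], h[1], "CA") for h, _ in pair_spec])
    b_idx = np.array([model.atom_index(b[0], b[1], "CA") for _, b in pair_spec])
    ref = model.coords
    rel = ref[h_idx] - ref[b_idx]

    def mean_dist(delta: float) -> float:
        return float(np.linalg.norm(rel + delta * normal, axis=1).mean())

    lo = -(d0 + motion.breathing_amplitude + 10.0)
    hi = d0 + motion.breathing_amplitude + 10.0
    opt = minimize_scalar(mean_dist, bounds=(lo, hi), method="bounded")
    floor = float(opt.fun)
    target_min = d0 - motion.breathing_amplitude
    if target_min <= floor:
        raise ValueError(
            f"breathing amplitude infeasible: minimum reachable mean pair "
            f"distance is {floor:.2f} A but d0 - A = {target_min:.2f} A")

    rng = np.random.default_rng(motion.seed)
    frames = np.empty((motion.n_frames, len(model), 3))
    t = np.arange(motion.n_frames)
    targets = d0 + motion.breathing_amplitude * np.sin(2 * np.pi * t / motion.breathing_period)
    delta_star = float(opt.x)
    for f, target in enumerate(targets):
        delta = brentq(lambda x: mean_dist(x) - target, delta_star, hi,
                       xtol=1e-10)
        coords = ref.copy()
        coords[helix_mask] += delta * normal
        if motion.jitter > 0:
            coords += rng.normal(scale=motion.jitter, size=coords.shape)
        frames[f] = coords
    traj = Trajectory(reference=model, frames=frames, dt=dt)
    return BreathingResult(trajectory=traj, pair_spec=list(pair_spec),
                           d0=d0, amplitude=motion.breathing_amplitude,
                           period=motion.breathing_period)
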