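"""Semi-essential hydrogen augmentation.

The hydropathic scorer does not need a full proton set: it uses polar
hydrogens (on N/O/S), hydrogens on unsaturated carbons, and hydrogens on
carbons alpha to a heteroatom.  They are placed from ideal internal geometry
(N-H 1.01 A, O-H 0.96 A, S-H 1.34 A, C-H 1.09 A); any hydrogens present in
the input are discarded first so placement is reproducible regardless of the
provenance of the structure.
"""

from __future__ import annotations

import numpy as np

from . import templates as T
from .geometry import place_internal, unit
from .structure import Atom, StructureModel

_SP3_ANGLES = {"C": 109.5, "N": 109.5, "O": 108.5, "S": 96.0}


def _perpendicular(v: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(unit(v), ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))


def _place_hydrogens(x: np.ndarray, neighbors: list[np.ndarray],
                     n_h: int, length: float) -> list[np.ndarray]:
    """Hydrogen positions around a parent with >= 2 heavy neighbours."""
    units = [unit(nb - x) for nb in neighbors]
    if len(units) >= 3 or (len(units) == 2 and n_h == 1):
        s = np.sum(units, axis=0)
        if np.linalg.norm(s) < 1e-6:
            d = _perpendicular(units[0])
        else:
            d = -unit(s)
        return [x + length * d]
    # two neighbours, two hydrogens: tetrahedral CH2 astride the bisector plane
    b = -unit(units[0] + units[1])
    p = unit(np.cross(units[0], units[1]))
    phi = np.radians(53.5)
    return [x + length * unit(np.cos(phi) * b + s * np.sin(phi) * p)
            for s in (+1.0, -1.0)]


def _place_on_terminal(x: np.ndarray, nb: np.ndarray, ref: np.ndarray | None,
                       n_h: int, length: float, sp2: bool,
                       element: str) -> list[np.ndarray]:
    """Hydrogens on an atom with exactly one heavy neighbour (hydroxyl, thiol,
    amide NH2, ammonium NH3, terminal methyl...)."""
    if ref is None:
        ref = nb + _perpendicular(x - nb)
    angle = np.radians(120.0 if sp2 else _SP3_ANGLES.get(element, 109.5))
    if n_h == 1:
        dihedrals = [180.0]
    elif n_h == 2:
        dihedrals = [0.0, 180.0] if sp2 else [180.0, 60.0]
    else:
        dihedrals = [180.0, 60.0, -60.0]
    return [place_internal(x, nb, ref, length, angle, np.radians(d))
            for d in dihedrals[:n_h]]


def add_semi_essential_hydrogens(model: StructureModel) -> StructureModel:
    """Return a copy of *model* with the semi-essential hydrogen set added.

    Existing hydrogens are discarded first.  Raises ValueError (naming the
    residue) when a heavy atom that should carry hydrogens has no bonded
    heavy neighbour to define the local frame.
    """
    keep = [i for i, a in enumerate(model.atoms) if a.element != "H"]
    remap = {old: new for new, old in enumerate(keep)}
    heavy_atoms = [model.atoms[i] for i in keep]
    # inherit the model's bond graph rather than re-deriving it from
    # coordinates, so perturbed geometries keep their topology
    heavy_bonds = [(remap[i], remap[j]) for i, j in model.covalent_bonds
                   if i in remap and j in remap]
    heavy = StructureModel(heavy_atoms, bonds=heavy_bonds)
    adj = heavy.adjacency()

    new_atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    index_map: dict[int, int] = {}

    def _emit(atom: Atom) -> int:
        new_atoms.append(atom)
        return len(new_atoms) - 1

    for i, a in enumerate(heavy.atoms):
        index_map[i] = _emit(a)
        if a.res_name not in T.STANDARD_RESIDUES:
            continue
        nbrs = adj[i]
        n_h = T.hydrogen_count(a.res_name, a.name, a.element, len(nbrs))
        if n_h == 0:
            continue
        nbr_elements = [heavy.atoms[j].element for j in nbrs]
        if not T.is_semi_essential_parent(a.res_name, a.name, a.element, nbr_elements):
            continue
        if not nbrs:
            raise ValueError(
                f"cannot place hydrogens on isolated atom {a.name} of "
                f"residue {a.chain}:{a.res_seq} ({a.res_name})")
        length = T.H_BOND_LENGTHS.get(a.element, 1.09)
        sp2 = T.is_sp2(a.res_name, a.name)
        nbr_pos = [heavy.atoms[j].coords for j in nbrs]
        if len(nbrs) == 1:
            j = nbrs[0]
            ref_pos = None
            for k in sorted(adj[j]):
                if k != i:
                    ref_pos = heavy.atoms[k].coords
                    break
            positions = _place_on_terminal(a.coords, nbr_pos[0], ref_pos,
                                           n_h, length, sp2, a.element)
        else:
            positions = _place_hydrogens(a.coords, nbr_pos, n_h, length)
        for k, pos in enumerate(positions):
            name = T.hydrogen_name(a.name, k, n_h)
            h_idx = _emit(Atom(serial=0, name=name, element="H",
                               res_name=a.res_name, res_seq=a.res_seq,
                               chain=a.chain, coords=pos))
            bonds.append((index_map[i], h_idx))

    for i, j in heavy.covalent_bonds:
        bonds.append((index_map[i], index_map[j]))
    for serial, atom in enumerate(new_atoms, start=1):
        atom.serial = serial
    out = StructureModel(new_atoms, bonds=bonds)
    out.segments = {k: list(v) for k, v in model.segments.items()}
    return out
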