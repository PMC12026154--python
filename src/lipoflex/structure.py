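"""Core data model: atoms, single-model structures and trajectories.

The ``StructureModel`` carries a covalent bond list derived from residue
topology templates (plus peptide bonds and auto-detected disulfides), which
the hydropathic scorer needs to exclude 1-2/1-3/1-4 pairs without relying on
CONECT records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import templates as T

PEPTIDE_BOND_MAX = 1.8   # A, C(i)-N(i+1)
DISULFIDE_MAX = 2.5      # A, SG-SG


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    coords: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain, self.res_seq)


class StructureModel:
    """An ordered collection of atoms with derived residues and bonds.

    Parameters
    ----------
    atoms
        Ordered atom list.
    bonds
        Optional explicit covalent bond list (pairs of atom indices).  When
        omitted, bonds are derived from the standard-residue templates,
        sequence-consecutive peptide bonds, SG-SG disulfides within 2.5 A,
        and hydrogen-to-nearest-heavy-atom attachment.
    """

    def __init__(self, atoms: list[Atom], bonds: list[tuple[int, int]] | None = None):
        if not atoms:
            raise ValueError("empty structure")
        self.atoms = list(atoms)
        self._index: dict[tuple[str, int, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain, a.res_seq, a.name)
            if key in self._index:
                raise ValueError(f"duplicate atom {key} in model")
            self._index[key] = i
        self.residues: list[tuple[str, int, str]] = []
        seen: set[tuple[str, int]] = set()
        for a in self.atoms:
            if a.residue_key not in seen:
                seen.add(a.residue_key)
                self.residues.append((a.chain, a.res_seq, a.res_name))
        self.covalent_bonds: list[tuple[int, int]] = (
            self._derive_bonds() if bonds is None else sorted({tuple(sorted(b)) for b in bonds})
        )
        for i, j in self.covalent_bonds:
            if i == j:
                raise ValueError("self-bond in bond list")
        # optional metadata set by generators (e.g. toy-protein segment map)
        self.segments: dict[str, list[tuple[str, int]]] = {}
        self.meta: dict = {}

    # ------------------------------------------------------------------ access

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array incongruent with atom list")
        for a, c in zip(self.atoms, coords):
            a.coords = c.copy()

    def atom_index(self, chain: str, res_seq: int, name: str) -> int:
        try:
            return self._index[(chain, res_seq, name)]
        except KeyError:
            raise KeyError(f"no atom {name} in residue {chain}:{res_seq}") from None

    def residue_atom_indices(self, chain: str, res_seq: int) -> list[int]:
        idx = [i for i, a in enumerate(self.atoms)
               if a.chain == chain and a.res_seq == res_seq]
        if not idx:
            raise KeyError(f"no residue {chain}:{res_seq} in model")
        return idx

    def residue_name(self, chain: str, res_seq: int) -> str:
        for c, s, n in self.residues:
            if c == chain and s == res_seq:
                return n
        raise KeyError(f"no residue {chain}:{res_seq} in model")

    def copy(self) -> "StructureModel":
        atoms = [replace(a, coords=a.coords.copy()) for a in self.atoms]
        m = StructureModel(atoms, bonds=list(self.covalent_bonds))
        m.segments = {k: list(v) for k, v in self.segments.items()}
        m.meta = dict(self.meta)
        return m

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        m = self.copy()
        m.set_coords(coords)
        return m

    # ------------------------------------------------------------------ bonds

    def _derive_bonds(self) -> list[tuple[int, int]]:
        bonds: set[tuple[int, int]] = set()

        def add(i: int, j: int) -> None:
            if i != j:
                bonds.add((min(i, j), max(i, j)))

        # intra-residue template bonds
        by_res: dict[tuple[str, int], dict[str, int]] = {}
        for i, a in enumerate(self.atoms):
            by_res.setdefault(a.residue_key, {})[a.name] = i
        for (chain, res_seq, res_name) in self.residues:
            names = by_res[(chain, res_seq)]
            if res_name in T.STANDARD_RESIDUES:
                for a, b in T.BACKBONE_BONDS + T.SIDECHAIN_BONDS[res_name]:
                    if a in names and b in names:
                        add(names[a], names[b])

        # peptide bonds between consecutive residues of the same chain
        for (c1, s1, _), (c2, s2, _) in zip(self.residues[:-1], self.residues[1:]):
            if c1 != c2:
                continue
            n1 = by_res[(c1, s1)]
            n2 = by_res[(c2, s2)]
            if "C" in n1 and "N" in n2:
                i, j = n1["C"], n2["N"]
                d = np.linalg.norm(self.atoms[i].coords - self.atoms[j].coords)
                if d <= PEPTIDE_BOND_MAX:
                    add(i, j)

        # disulfides
        sg = [i for i, a in enumerate(self.atoms)
              if a.res_name == "CYS" and a.name == "SG"]
        for k, i in enumerate(sg):
            for j in sg[k + 1:]:
                d = np.linalg.norm(self.atoms[i].coords - self.atoms[j].coords)
                if d <= DISULFIDE_MAX:
                    add(i, j)

        # hydrogens attach to the nearest heavy atom of the same residue
        for i, a in enumerate(self.atoms):
            if a.element != "H":
                continue
            best, best_d = None, np.inf
            for j in by_res[a.residue_key].values():
                other = self.atoms[j]
                if other.element == "H":
                    continue
                d = np.linalg.norm(a.coords - other.coords)
                if d < best_d:
                    best, best_d = j, d
            if best is not None and best_d <= 1.6:
                add(i, best)

        return sorted(bonds)

    def adjacency(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.atoms]
        for i, j in self.covalent_bonds:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def bonded_within(self, depth: int) -> set[tuple[int, int]]:
        """All atom pairs (i<j) whose bond-graph distance is <= *depth*."""
        adj = self.adjacency()
        out: set[tuple[int, int]] = set()
        for start in range(len(self.atoms)):
            frontier = {start}
            seen = {start}
            for _ in range(depth):
                nxt: set[int] = set()
                for u in frontier:
                    for v in adj[u]:
                        if v not in seen:
                            seen.add(v)
                            nxt.add(v)
                frontier = nxt
            for v in seen:
                if v > start:
                    out.add((start, v))
        return out

    # ------------------------------------------------------------------ checks

    def validate(self) -> None:
        """Raise ValueError on invariant violations."""
        coords = self.coords
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates in model")
        for a in self.atoms:
            if not a.element:
                raise ValueError(f"atom {a.name} in {a.chain}:{a.res_seq} has empty element")
        # backbone completeness, terminal residues excused
        chain_first_last: dict[str, tuple[int, int]] = {}
        order: dict[str, list[int]] = {}
        for c, s, _ in self.residues:
            order.setdefault(c, []).append(s)
        for c, seqs in order.items():
            chain_first_last[c] = (seqs[0], seqs[-1])
        by_res: dict[tuple[str, int], set[str]] = {}
        for a in self.atoms:
            by_res.setdefault(a.residue_key, set()).add(a.name)
        for (c, s, rn) in self.residues:
            if rn not in T.STANDARD_RESIDUES:
                continue
            missing = {"N", "CA", "C"} - by_res[(c, s)]
            if missing and s not in chain_first_last[c]:
                raise ValueError(f"residue {c}:{s} ({rn}) missing backbone atoms {sorted(missing)}")


@dataclass
class Trajectory:
    """Ordered coordinate frames over a fixed atom set.

    ``frames`` has shape (n_frames, n_atoms, 3); ``dt`` is the frame spacing
    in picoseconds.
    """

    reference: StructureModel
    frames: np.ndarray
    dt: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (len(self.reference), 3):
            raise ValueError("frames incongruent with reference atom set")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_model(self, i: int) -> StructureModel:
        return self.reference.with_coords(self.frames[i])

    def atom_indices(self, selection: str | None = "CA") -> np.ndarray:
        """Indices of atoms whose name matches *selection* (None = all)."""
        if selection is None:
            return np.arange(len(self.reference))
        idx = np.array([i for i, a in enumerate(self.reference.atoms)
                        if a.name == selection], dtype=int)
        if idx.size == 0:
            raise ValueError(f"empty selection {selection!r}")
        return idx
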