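"""PDB reading/writing into the package's data model.

Single-model PDB files are the structure format; multi-model PDB files
(MODEL/ENDMDL blocks) are the canonical text trajectory format, which keeps
fixtures diffable.  Parsing and serialisation are delegated to biotite; the
filtering policy (waters/hetero dropped, first altloc kept, insertion codes
rejected) and the bond derivation live here.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import biotite.structure as _bts
from biotite.structure.io.pdb import PDBFile

from . import templates as T
from .structure import Atom, StructureModel, Trajectory


class PDBParseError(ValueError):
    pass


def _find_bad_line(path: str | Path) -> int | None:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                return lineno
            try:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
                int(line[22:26])
            except ValueError:
                return lineno
    return None


def _read_pdb_file(path: str | Path) -> PDBFile:
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - depends on file content
        raise PDBParseError(f"cannot read PDB file {path}: {exc}") from exc


def _array_to_atoms(arr, keep_hydrogens: bool) -> list[Atom]:
    atoms: list[Atom] = []
    serials = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    occ = (arr.occupancy if "occupancy" in arr.get_annotation_categories()
           else np.ones(arr.array_length()))
    bf = (arr.b_factor if "b_factor" in arr.get_annotation_categories()
          else np.zeros(arr.array_length()))
    for i in range(arr.array_length()):
        element = str(arr.element[i]).strip().upper()
        name = str(arr.atom_name[i]).strip()
        if not element:
            element = T.element_of("", name)
        if element == "H" and not keep_hydrogens:
            continue
        atoms.append(Atom(
            serial=int(serials[i]),
            name=name,
            element=element,
            res_name=str(arr.res_name[i]).strip(),
            res_seq=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]).strip() or "A",
            coords=np.asarray(arr.coord[i], dtype=float),
            occupancy=float(occ[i]),
            b_factor=float(bf[i]),
        ))
    return atoms


def _filter(arr, keep_waters: bool, keep_hetero: bool):
    if np.any(arr.ins_code != ""):
        bad = np.unique(arr.res_id[arr.ins_code != ""])
        raise PDBParseError(
            f"insertion codes are not supported (residues {bad.tolist()})")
    mask = np.ones(arr.array_length(), dtype=bool)
    is_water = np.isin(arr.res_name, list(T.WATER_RESIDUES))
    is_standard = np.isin(arr.res_name, list(T.STANDARD_RESIDUES))
    if not keep_waters:
        mask &= ~is_water
    if not keep_hetero:
        mask &= is_standard | (keep_waters & is_water)
    return arr[mask]


def read_pdb(path: str | Path, *, keep_waters: bool = False,
             keep_hetero: bool = False, keep_hydrogens: bool = False,
             model: int = 1) -> StructureModel:
    """Read a single-model PDB file.

    Waters (HOH/WAT) and non-protein HETATM records are dropped by default;
    hydrogens present in the input are dropped (the scorer rebuilds its own
    semi-essential set).  Alternate location A/blank is kept, others dropped.
    """
    pdb = _read_pdb_file(path)
    try:
        arr = pdb.get_structure(model=model, altloc="first",
                                extra_fields=["atom_id", "occupancy", "b_factor"])
    except Exception as exc:
        lineno = _find_bad_line(path)
        hint = f" (first malformed record at line {lineno})" if lineno else ""
        raise PDBParseError(f"malformed PDB file {path}{hint}: {exc}") from exc
    arr = _filter(arr, keep_waters, keep_hetero)
    atoms = _array_to_atoms(arr, keep_hydrogens)
    if not atoms:
        raise PDBParseError(f"no protein atoms in {path}")
    return StructureModel(atoms)


def read_multimodel_trajectory(path: str | Path, dt: float = 1.0, *,
                               keep_hydrogens: bool = True) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (reference = first model)."""
    pdb = _read_pdb_file(path)
    n_models = pdb.get_model_count()
    if n_models < 1:
        raise PDBParseError(f"no models in {path}")
    first = pdb.get_structure(model=1, altloc="first",
                              extra_fields=["atom_id", "occupancy", "b_factor"])
    first = _filter(first, keep_waters=False, keep_hetero=False)
    atoms = _array_to_atoms(first, keep_hydrogens)
    if not atoms:
        raise PDBParseError(f"no protein atoms in {path}")
    reference = StructureModel(atoms)
    try:
        coords = pdb.get_coord(model=None)
    except Exception:
        # name the offending model for the error message
        counts = []
        for m in range(1, n_models + 1):
            counts.append(pdb.get_structure(model=m).array_length())
        bad = [m for m, c in enumerate(counts, start=1) if c != counts[0]]
        raise PDBParseError(
            f"atom count mismatch across models in {path}: model(s) {bad} "
            f"differ from model 1") from None
    # apply the same water/hetero/hydrogen mask to every frame
    raw = pdb.get_structure(model=1, altloc="first",
                            extra_fields=["atom_id", "occupancy", "b_factor"])
    mask = np.ones(raw.array_length(), dtype=bool)
    if np.any(raw.ins_code != ""):
        raise PDBParseError("insertion codes are not supported")
    mask &= ~np.isin(raw.res_name, list(T.WATER_RESIDUES))
    mask &= np.isin(raw.res_name, list(T.STANDARD_RESIDUES))
    if not keep_hydrogens:
        mask &= np.char.upper(np.char.strip(raw.element)) != "H"
    frames = coords[:, mask, :]
    if frames.shape[1] != len(reference):
        raise PDBParseError(f"inconsistent filtering of {path}")
    return Trajectory(reference=reference, frames=frames, dt=dt)


def _model_to_array(model: StructureModel):
    n = len(model)
    arr = _bts.AtomArray(n)
    arr.coord = model.coords
    arr.chain_id = np.array([a.chain for a in model.atoms])
    arr.res_id = np.array([a.res_seq for a in model.atoms])
    arr.res_name = np.array([a.res_name for a in model.atoms])
    arr.atom_name = np.array([a.name for a in model.atoms])
    arr.element = np.array([a.element for a in model.atoms])
    arr.hetero = ~np.isin(arr.res_name, list(T.STANDARD_RESIDUES))
    arr.set_annotation("occupancy", np.array([a.occupancy for a in model.atoms]))
    arr.set_annotation("b_factor", np.array([a.b_factor for a in model.atoms]))
    return arr


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-column PDB ATOM records (coordinates to 3 decimals)."""
    pdb = PDBFile()
    pdb.set_structure(_model_to_array(model))
    pdb.write(str(path))


def write_multimodel_trajectory(traj: Trajectory, path: str | Path) -> None:
    arr = _model_to_array(traj.reference)
    stack = _bts.AtomArrayStack(traj.n_frames, len(traj.reference))
    for cat in arr.get_annotation_categories():
        stack.set_annotation(cat, arr.get_annotation(cat))
    stack.coord = traj.frames.copy()
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
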