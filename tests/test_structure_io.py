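"""Structure/trajectory reading and writing: round trips, filtering,
bond derivation."""

import numpy as np
import pytest

import lipoflex as lf
from lipoflex.io import PDBParseError
from lipoflex.structure import Atom, StructureModel, Trajectory


def test_write_read_roundtrip_identity(tmp_path):
    model = lf.make_peptide("AAA", "extended")
    path = tmp_path / "tri.pdb"
    lf.write_pdb(model, path)
    back = lf.read_pdb(path)
    assert len(back) == len(model)
    assert [a.name for a in back.atoms] == [a.name for a in model.atoms]
    assert [a.res_seq for a in back.atoms] == [a.res_seq for a in model.atoms]
    assert np.abs(back.coords - model.coords).max() <= 1e-3


def test_water_and_ligand_filtering(tmp_path):
    lines = []
    serial = 1
    model = lf.make_peptide("AA", "extended")  # 11 atoms incl. OXT
    lf.write_pdb(model, tmp_path / "prot.pdb")
    text = (tmp_path / "prot.pdb").read_text().splitlines()
    atom_lines = [l for l in text if l.startswith("ATOM")][:10]
    for i in range(2):
        atom_lines.append(
            f"HETATM{900 + i:5d}  O   HOH A{90 + i:4d}    "
            f"{10.0 + i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           O")
    (tmp_path / "mix.pdb").write_text("\n".join(atom_lines) + "\nEND\n")
    back = lf.read_pdb(tmp_path / "mix.pdb")
    assert len(back) == 10
    assert all(a.res_name != "HOH" for a in back.atoms)
    kept = lf.read_pdb(tmp_path / "mix.pdb", keep_waters=True, keep_hetero=True)
    assert len(kept) == 12


def test_malformed_record_reports_line(tmp_path):
    lf.write_pdb(lf.make_peptide("AA", "extended"), tmp_path / "a.pdb")
    lines = (tmp_path / "a.pdb").read_text().splitlines()
    atom_idx = next(i for i, l in enumerate(lines) if l.startswith("ATOM"))
    bad = lines[atom_idx + 2]
    lines[atom_idx + 2] = bad[:30] + "  xx.xxx" + bad[38:]
    (tmp_path / "bad.pdb").write_text("\n".join(lines) + "\n")
    with pytest.raises(PDBParseError, match="line"):
        lf.read_pdb(tmp_path / "bad.pdb")


def test_empty_protein_error(tmp_path):
    (tmp_path / "w.pdb").write_text(
        "HETATM    1  O   HOH A   1      10.000   0.000   0.000  1.00  0.00           O\nEND\n")
    with pytest.raises(PDBParseError, match="no protein"):
        lf.read_pdb(tmp_path / "w.pdb")


def test_insertion_codes_rejected(tmp_path):
    lf.write_pdb(lf.make_peptide("AA", "extended"), tmp_path / "a.pdb")
    lines = (tmp_path / "a.pdb").read_text().splitlines()
    out = []
    for l in lines:
        if l.startswith("ATOM") and l[22:26].strip() == "2":
            l = l[:26] + "A" + l[27:]
        out.append(l)
    (tmp_path / "ins.pdb").write_text("\n".join(out) + "\n")
    with pytest.raises(PDBParseError, match="insertion"):
        lf.read_pdb(tmp_path / "ins.pdb")


def test_multimodel_rigid_and_single(tmp_path):
    model = lf.make_peptide("AGA", "extended")
    traj = Trajectory(model, np.repeat(model.coords[None], 5, axis=0))
    lf.write_multimodel_trajectory(traj, tmp_path / "t.pdb")
    back = lf.read_multimodel_trajectory(tmp_path / "t.pdb")
    assert back.n_frames == 5
    assert np.abs(back.frames - back.frames[0]).max() == 0.0

    lf.write_pdb(model, tmp_path / "one.pdb")
    single = lf.read_multimodel_trajectory(tmp_path / "one.pdb")
    assert single.n_frames == 1


def test_multimodel_roundtrip_precision(tmp_path, toy):
    motion = lf.MotionSpec(sigmas=0.5, n_frames=100, seed=11)
    traj = lf.make_harmonic_trajectory(toy, motion)
    lf.write_multimodel_trajectory(traj, tmp_path / "h.pdb")
    back = lf.read_multimodel_trajectory(tmp_path / "h.pdb")
    assert back.n_frames == 100
    assert np.abs(back.frames - traj.frames).max() <= 1e-3


def test_multimodel_atom_mismatch_names_model(tmp_path):
    model = lf.make_peptide("AG", "extended")
    traj = Trajectory(model, np.repeat(model.coords[None], 3, axis=0))
    lf.write_multimodel_trajectory(traj, tmp_path / "t.pdb")
    lines = (tmp_path / "t.pdb").read_text().splitlines()
    # drop one atom from the second model
    out, in_model2, dropped = [], False, False
    for l in lines:
        if l.startswith("MODEL") and l.split()[1] == "2":
            in_model2 = True
        if in_model2 and not dropped and l.startswith("ATOM"):
            dropped = True
            continue
        out.append(l)
    (tmp_path / "bad.pdb").write_text("\n".join(out) + "\n")
    with pytest.raises(PDBParseError):
        lf.read_multimodel_trajectory(tmp_path / "bad.pdb")


def test_disulfide_detection_and_bond_invariants():
    # two Cys placed so the SG atoms sit 2.0 A apart
    a = lf.make_peptide("C", "extended")
    b = lf.make_peptide("C", "extended", start_seq=10)
    sg_a = a.atoms[a.atom_index("A", 1, "SG")].coords
    sg_b = b.atoms[b.atom_index("A", 10, "SG")].coords
    shift = (sg_a - sg_b) + np.array([2.0, 0.0, 0.0])
    atoms = [*a.atoms]
    for at in b.atoms:
        at.coords = at.coords + shift
        atoms.append(at)
    for s, at in enumerate(atoms, start=1):
        at.serial = s
    model = StructureModel(atoms)
    i = model.atom_index("A", 1, "SG")
    j = model.atom_index("A", 10, "SG")
    assert (min(i, j), max(i, j)) in model.covalent_bonds
    # bond list: symmetric by construction, no self bonds
    assert all(i != j for i, j in model.covalent_bonds)
    # disulfide-bonded cysteines get no thiol hydrogen
    with_h = lf.add_semi_essential_hydrogens(model)
    names = [at.name for at in with_h.atoms if at.element == "H"]
    assert "HG" not in names


def test_duplicate_atom_key_rejected():
    at = Atom(1, "CA", "C", "GLY", 1, "A", np.zeros(3))
    at2 = Atom(2, "CA", "C", "GLY", 1, "A", np.ones(3))
    with pytest.raises(ValueError, match="duplicate"):
        StructureModel([at, at2])
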