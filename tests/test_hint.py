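"""Hydropathic scoring engine: formula, classification, aggregation."""

import numpy as np
import pytest

import lipoflex as lf
from lipoflex.geometry import rotation_about
from lipoflex.hint import (HydropathyAssignment, HydropathyParams, hint_total,
                           pair_score, residue_interactions)
from lipoflex.structure import Atom, StructureModel

from conftest import brute_force_hint


def _two_atom_model(distance):
    return StructureModel([
        Atom(1, "CA", "C", "GLY", 1, "A", np.zeros(3)),
        Atom(2, "CA", "C", "GLY", 1, "B", np.array([distance, 0.0, 0.0])),
    ])


def _manual_assignment(a, sasa, classes=None, roles=None):
    n = len(a)
    return HydropathyAssignment(
        a=np.asarray(a, dtype=float), sasa=np.asarray(sasa, dtype=float),
        polarity_class=classes or ["hydrophobic"] * n,
        hbond_role=roles or ["none"] * n)


@pytest.fixture(scope="module")
def bare_params():
    return HydropathyParams(table={})


def test_unit_pair_score(bare_params):
    model = _two_atom_model(0.0)
    asn = _manual_assignment([1.0, 1.0], [1.0, 1.0])
    rec = pair_score(model, 0, 1, asn, bare_params, excluded=set())
    assert rec.b_ij == pytest.approx(1.0)
    assert rec.klass == "hydrophobic"


def test_bilinearity_in_sasa(bare_params):
    model = _two_atom_model(3.0)
    b1 = pair_score(model, 0, 1, _manual_assignment([1, 1], [1, 1]),
                    bare_params, excluded=set()).b_ij
    b4 = pair_score(model, 0, 1, _manual_assignment([1, 1], [2, 2]),
                    bare_params, excluded=set()).b_ij
    assert b4 == pytest.approx(4 * b1)


def test_mixed_polarity_is_desolvation(bare_params):
    model = _two_atom_model(3.0)
    asn = _manual_assignment([0.5, -0.8], [10.0, 10.0],
                             classes=["hydrophobic", "polar-neutral"])
    rec = pair_score(model, 0, 1, asn, bare_params, excluded=set())
    assert rec.b_ij < 0
    assert rec.klass == "desolvation"


def test_like_charge_pairs_are_unfavorable(bare_params):
    model = _two_atom_model(4.0)
    asn = _manual_assignment([-1.1, -1.1], [5.0, 5.0], classes=["acid", "acid"],
                             roles=["acceptor", "acceptor"])
    rec = pair_score(model, 0, 1, asn, bare_params, excluded=set())
    assert rec.klass == "electrostatic-unfavorable"
    assert rec.b_ij < 0
    asn2 = _manual_assignment([-1.1, -1.0], [5.0, 5.0], classes=["acid", "base"])
    rec2 = pair_score(model, 0, 1, asn2, bare_params, excluded=set())
    assert rec2.klass == "electrostatic-favorable"
    assert rec2.b_ij > 0


def test_monotone_burial(bare_params):
    # frozen SASA: halving the separation strictly increases the pair score
    asn = _manual_assignment([0.5, 0.5], [8.0, 8.0])
    b_far = pair_score(_two_atom_model(8.0), 0, 1, asn, bare_params,
                       excluded=set()).b_ij
    b_near = pair_score(_two_atom_model(4.0), 0, 1, asn, bare_params,
                        excluded=set()).b_ij
    assert b_near > b_far > 0


def test_excluded_pair_raises(default_params):
    model = lf.make_peptide("A", "extended")
    asn = _manual_assignment([1.0] * len(model), [1.0] * len(model))
    i = model.atom_index("A", 1, "N")
    j = model.atom_index("A", 1, "CA")
    with pytest.raises(ValueError, match="covalently"):
        pair_score(model, i, j, asn, default_params)


def test_missing_parameter_entry_lists_atom(default_params):
    model = StructureModel([Atom(1, "XQ", "C", "ALA", 1, "A", np.zeros(3)),
                            Atom(2, "CA", "C", "ALA", 1, "A", np.ones(3))])
    with pytest.raises(KeyError, match="ALA/XQ"):
        lf.assign_hydropathy(model, default_params)


@pytest.mark.parametrize("seed", range(10))
def test_brute_force_oracle(default_params, seed):
    """hint_total equals an independently coded all-pairs sum on small
    random peptide systems, and the class components close exactly."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("GASCTVL"), size=3))
    conf = ["extended", "helix"][seed % 2]
    pep = lf.make_peptide(seq, conf)
    pep.set_coords(pep.coords + rng.normal(scale=0.1, size=(len(pep), 3)))
    model = lf.add_semi_essential_hydrogens(pep)
    assert len(model) <= 50
    asn = lf.assign_hydropathy(model, default_params)
    table = hint_total(model, default_params, assignment=asn)
    ref_total, ref_components = brute_force_hint(model, default_params, asn)
    scale = max(1.0, abs(ref_total))
    assert abs(table.total_B - ref_total) <= 1e-10 * scale
    for k, v in ref_components.items():
        assert abs(table.components[k] - v) <= 1e-10 * scale
    assert sum(table.components.values()) == table.total_B


def test_atom_permutation_invariance(default_params):
    model = lf.add_semi_essential_hydrogens(lf.make_peptide("ASA", "helix"))
    asn = lf.assign_hydropathy(model, default_params)
    base = hint_total(model, default_params, assignment=asn)
    rng = np.random.default_rng(5)
    perm = rng.permutation(len(model))
    inv = np.argsort(perm)
    atoms = [model.atoms[p] for p in perm]
    bonds = [(int(inv[i]), int(inv[j])) for i, j in model.covalent_bonds]
    shuffled = StructureModel(atoms, bonds=bonds)
    asn2 = HydropathyAssignment(a=asn.a[perm], sasa=asn.sasa[perm],
                                polarity_class=[asn.polarity_class[p] for p in perm],
                                hbond_role=[asn.hbond_role[p] for p in perm])
    out = hint_total(shuffled, default_params, assignment=asn2)
    assert out.total_B == pytest.approx(base.total_B, rel=1e-10)


def test_rigid_motion_invariance(default_params):
    model = lf.add_semi_essential_hydrogens(lf.make_peptide("ASA", "helix"))
    base = hint_total(model, default_params)
    R = rotation_about([0.3, 1.0, -0.2], 2.1)
    moved = model.with_coords(model.coords @ R.T + np.array([7.0, 1.0, -4.0]))
    out = hint_total(moved, default_params)
    assert out.total_B == pytest.approx(base.total_B, rel=1e-9)
    for k in base.components:
        assert out.components[k] == pytest.approx(base.components[k],
                                                  rel=1e-9, abs=1e-9)


def _facing_pair(res2: str):
    """Two single-residue molecules with side chains facing across a ~4 A gap."""
    m1 = lf.make_peptide("L", "extended")
    m2 = lf.make_peptide(res2, "extended")
    ca1 = m1.atoms[m1.atom_index("A", 1, "CA")].coords
    cb1 = m1.atoms[m1.atom_index("A", 1, "CB")].coords
    direction = (cb1 - ca1) / np.linalg.norm(cb1 - ca1)
    R = rotation_about(np.cross(direction, [0, 0, 1.0]), np.pi)
    sc2 = "CG" if res2 == "L" else "OG"
    anchor2 = m2.atoms[m2.atom_index("A", 1, sc2)].coords
    target = cb1 + 5.5 * direction
    atoms = [a for a in m1.atoms]
    for a in m2.atoms:
        pos = (a.coords - anchor2) @ R.T + target
        atoms.append(Atom(a.serial + 100, a.name, a.element, a.res_name,
                          a.res_seq, "B", pos))
    return lf.add_semi_essential_hydrogens(StructureModel(atoms))


def test_hydrophobic_contact_fixture(default_params):
    model = _facing_pair("L")
    table = hint_total(model, default_params)
    assert table.components["hydrophobic"] > 0
    assert table.components["hydrogen-bond"] == 0.0


def test_serine_substitution_weakens_hydrophobic_contact(default_params):
    leu = hint_total(_facing_pair("L"), default_params)
    ser = hint_total(_facing_pair("S"), default_params)
    assert ser.components["hydrophobic"] < leu.components["hydrophobic"]


def test_single_glycine_pair_graph(default_params):
    """On one Gly residue, every heavy-atom pair lies within bond depth 3;
    the only admissible pairs involve hydrogens, matching the brute-force
    enumeration."""
    model = lf.add_semi_essential_hydrogens(lf.make_peptide("G", "extended"))
    asn = lf.assign_hydropathy(model, default_params)
    table = hint_total(model, default_params, assignment=asn)
    for rec in table.records:
        assert "H" in (model.atoms[rec.i].element, model.atoms[rec.j].element)
    ref_total, _ = brute_force_hint(model, default_params, asn)
    assert table.total_B == pytest.approx(ref_total, abs=1e-12)


def test_residue_interactions_report(default_params):
    model = lf.add_semi_essential_hydrogens(lf.make_peptide("AGA", "extended"))
    assert residue_interactions(model, default_params, "A", 2) == []

    model = lf.add_semi_essential_hydrogens(lf.make_peptide("AYA", "helix"))
    partners = residue_interactions(model, default_params, "A", 2)
    assert partners
    keys = {(g.partner[0], g.partner[1]) for g in partners}
    assert keys <= {("A", 1), ("A", 3)}
    totals = [abs(g.total) for g in partners]
    assert totals == sorted(totals, reverse=True)
    for g in partners:
        assert g.total == pytest.approx(sum(g.components.values()))
    with pytest.raises(KeyError):
        residue_interactions(model, default_params, "A", 99)


def test_params_table_consistency(default_params):
    """The shipped TSV is exactly the table the builder generates, and every
    semi-essential hydrogen of every residue has an entry."""
    assert default_params.table == lf.build_default_params().table
    from lipoflex import templates as T
    for res in sorted(T.STANDARD_RESIDUES):
        for atom in sorted(T.heavy_atom_names(res)):
            default_params.lookup(res, atom)
        for h, _parent in T.semi_essential_hydrogen_names(res):
            default_params.lookup(res, h)
        for atom in ("OXT",):
            default_params.lookup(res, atom)
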