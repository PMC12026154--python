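"""Intramolecular hydropathic (HINT-style) interaction scoring.

Every atom pair (i, j) that is neither covalently coupled (bond-graph
distance <= 3) nor beyond the non-bonded cutoff contributes a
micro-interaction score

    b_ij = S_i * a_i * S_j * a_j * R(r_ij),      R(r) = exp(-r / 1 A)

where S is the atom's solvent-accessible surface area in the whole-protein
context and a is its hydrophobic atom constant (sign carries polarity:
positive hydrophobic, negative polar).  The total score B = sum b_ij is
decomposed into hydrogen-bond, electrostatic (favorable/unfavorable),
hydrophobic and desolvation classes.  Like-charged acid-acid and base-base
pairs are forced negative (repulsive Coulombic), matching the physical
reading of the decomposition; all other classes keep the sign of the raw
product.

The atom constants shipped with the package are authored from residue
chemistry (octanol/water logP fragment reasoning); they are internally
consistent but are not the proprietary HINT parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import templates as T
from .sasa import compute_sasa
from .structure import StructureModel, Trajectory

POLARITY_CLASSES = ("hydrophobic", "polar-neutral", "acid", "base", "amphoteric")
HBOND_ROLES = ("donor", "acceptor", "both", "none")
INTERACTION_CLASSES = ("hydrogen-bond", "electrostatic-favorable", "hydrophobic",
                       "electrostatic-unfavorable", "desolvation")

BACKBONE_SET = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class AtomParam:
    a: float
    polarity_class: str
    hbond_role: str


@dataclass
class HydropathyParams:
    """Parameter table plus the knobs of the scoring engine."""

    table: dict[tuple[str, str], AtomParam]
    probe_radius: float = 1.4
    sphere_points: int = 256
    distance_decay: str = "exp"
    decay_length: float = 1.0      # A
    exclusion_bond_depth: int = 3
    cutoff: float = 9.0            # A (the MD non-bonded cutoff, reused)
    hbond_h_acceptor_max: float = 2.5   # A
    hbond_angle_min: float = 120.0      # degrees, donor-H-acceptor

    def lookup(self, res_name: str, atom_name: str) -> AtomParam:
        p = self.table.get((res_name, atom_name)) or self.table.get(("*", atom_name))
        if p is None:
            raise KeyError(f"no hydropathy parameters for ({res_name}, {atom_name})")
        return p

    def decay(self, r: np.ndarray | float):
        if self.distance_decay == "exp":
            return np.exp(-np.asarray(r) / self.decay_length)
        raise ValueError(f"unknown distance decay {self.distance_decay!r}")


# --------------------------------------------------------------------------
# default parameter table

_CARBONYL_CARBONS = {("ASN", "CG"), ("GLN", "CD"), ("ASP", "CG"),
                     ("GLU", "CD"), ("ARG", "CZ")}


def _sidechain_param(res: str, atom: str) -> AtomParam:
    element = T.element_of(res, atom)
    nbr_elems = [T.element_of(res, n) for n in T.template_heavy_neighbors(res, atom)]
    het = any(e in ("N", "O", "S") for e in nbr_elems)
    if element == "C":
        if (res, atom) in _CARBONYL_CARBONS:
            return AtomParam(-0.3, "polar-neutral", "none")
        if atom in T.SP2_CARBONS.get(res, frozenset()):
            return AtomParam(0.1 if het else 0.3, "hydrophobic", "none")
        return AtomParam(0.1 if het else 0.5, "hydrophobic", "none")
    if element == "N":
        if res == "LYS" and atom == "NZ":
            return AtomParam(-1.2, "base", "donor")
        if res == "ARG":
            return AtomParam(-1.0, "base", "donor")
        if res == "HIS":
            return AtomParam(-0.5, "amphoteric",
                             "acceptor" if atom == "ND1" else "donor")
        if res == "TRP":
            return AtomParam(-0.4, "polar-neutral", "donor")
        return AtomParam(-0.7, "polar-neutral", "donor")   # Asn/Gln amide N
    if element == "O":
        if res in ("ASP", "GLU"):
            return AtomParam(-1.1, "acid", "acceptor")
        if atom in ("OG", "OG1", "OH"):
            return AtomParam(-0.7, "polar-neutral", "both")
        return AtomParam(-0.8, "polar-neutral", "acceptor")  # Asn/Gln carbonyl
    if element == "S":
        if res == "MET":
            return AtomParam(0.3, "hydrophobic", "none")
        return AtomParam(-0.2, "polar-neutral", "both")      # Cys thiol
    raise ValueError(f"unexpected element {element} for {res} {atom}")


def build_default_params() -> HydropathyParams:
    """Construct the shipped parameter table from residue chemistry rules."""
    table: dict[tuple[str, str], AtomParam] = {
        ("*", "N"): AtomParam(-0.6, "polar-neutral", "donor"),
        ("PRO", "N"): AtomParam(-0.6, "polar-neutral", "none"),
        ("*", "CA"): AtomParam(0.1, "hydrophobic", "none"),
        ("*", "C"): AtomParam(-0.3, "polar-neutral", "none"),
        ("*", "O"): AtomParam(-0.8, "polar-neutral", "acceptor"),
        ("*", "OXT"): AtomParam(-1.1, "acid", "acceptor"),
    }
    # backbone hydrogens (amide H, alpha H; terminal variants share entries)
    for h in ("H", "H1", "H2", "H3"):
        table[("*", h)] = AtomParam(-0.1, "polar-neutral", "none")
    for h in ("HA", "HA1", "HA2"):
        table[("*", h)] = AtomParam(0.1, "hydrophobic", "none")
    for res in sorted(T.STANDARD_RESIDUES):
        for atom in sorted(T.sidechain_atom_names(res)):
            table[(res, atom)] = _sidechain_param(res, atom)
        for h_name, parent in T.semi_essential_hydrogen_names(res):
            if parent in BACKBONE_SET:
                continue
            parent_param = table[(res, parent)]
            if parent_param.a > 0:
                table[(res, h_name)] = AtomParam(0.1, "hydrophobic", "none")
            else:
                klass = "base" if parent_param.polarity_class == "base" else "polar-neutral"
                table[(res, h_name)] = AtomParam(-0.1, klass, "none")
    return HydropathyParams(table=table)


def write_params_tsv(params: HydropathyParams, path: str | Path) -> None:
    rows = [{"res_name": r, "atom_name": a, "a": p.a,
             "polarity_class": p.polarity_class, "hbond_role": p.hbond_role}
            for (r, a), p in sorted(params.table.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_params(path: str | Path | None = None) -> HydropathyParams:
    """Load a parameter table from TSV (default: the table shipped with the
    package in ``lipoflex/data/hint_params.tsv``)."""
    if path is None:
        ref = resources.files("lipoflex").joinpath("data/hint_params.tsv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    table: dict[tuple[str, str], AtomParam] = {}
    for row in df.itertuples(index=False):
        if row.polarity_class not in POLARITY_CLASSES:
            raise ValueError(f"unknown polarity class {row.polarity_class!r}")
        if row.hbond_role not in HBOND_ROLES:
            raise ValueError(f"unknown hbond role {row.hbond_role!r}")
        table[(str(row.res_name), str(row.atom_name))] = AtomParam(
            float(row.a), str(row.polarity_class), str(row.hbond_role))
    return HydropathyParams(table=table)


# --------------------------------------------------------------------------
# assignment

@dataclass
class HydropathyAssignment:
    """Per-atom hydropathy state: constants, SASA, classes, roles."""

    a: np.ndarray
    sasa: np.ndarray
    polarity_class: list[str]
    hbond_role: list[str]

    def __post_init__(self):
        if np.any(self.sasa < 0):
            raise ValueError("negative SASA in assignment")

    @property
    def total_sasa(self) -> float:
        return float(self.sasa.sum())


def assign_hydropathy(model: StructureModel,
                      params: HydropathyParams) -> HydropathyAssignment:
    """Assign (a_i, S_i, class, role) to every atom.  Expects the
    semi-essential hydrogens to be present already."""
    a = np.empty(len(model))
    classes: list[str] = []
    roles: list[str] = []
    missing: list[tuple[str, str]] = []
    for i, atom in enumerate(model.atoms):
        try:
            p = params.lookup(atom.res_name, atom.name)
        except KeyError:
            missing.append((atom.res_name, atom.name))
            continue
        a[i] = p.a
        classes.append(p.polarity_class)
        roles.append(p.hbond_role)
    if missing:
        raise KeyError("no hydropathy parameters for: "
                       + ", ".join(f"{r}/{n}" for r, n in sorted(set(missing))))
    sasa = compute_sasa(model, probe_radius=params.probe_radius,
                        n_points=params.sphere_points)
    return HydropathyAssignment(a=a, sasa=sasa, polarity_class=classes,
                                hbond_role=roles)


# --------------------------------------------------------------------------
# pairwise scoring

@dataclass
class InteractionRecord:
    i: int
    j: int
    atom_i: tuple[str, int, str]   # (chain, res_seq, atom name)
    atom_j: tuple[str, int, str]
    r_ij: float
    b_ij: float
    klass: str


class _HBondGeometry:
    """Precomputed donor-hydrogen topology for the H-bond geometry test."""

    def __init__(self, model: StructureModel, assignment: HydropathyAssignment):
        self.model = model
        self.assignment = assignment
        self.h_of: dict[int, list[int]] = {}
        self.parent_of: dict[int, int] = {}
        for i, j in model.covalent_bonds:
            for h, heavy in ((i, j), (j, i)):
                if model.atoms[h].element == "H" and model.atoms[heavy].element != "H":
                    self.h_of.setdefault(heavy, []).append(h)
                    self.parent_of[h] = heavy

    def _geometry_ok(self, donor: int, h: int, acceptor: int,
                     max_ha: float, min_angle: float) -> bool:
        coords = self.model.coords
        ha = coords[acceptor] - coords[h]
        d_ha = np.linalg.norm(ha)
        if d_ha > max_ha or d_ha < 1e-6:
            return False
        hd = coords[donor] - coords[h]
        cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * d_ha)
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return angle >= min_angle

    def is_hbond(self, i: int, j: int, max_ha: float, min_angle: float) -> bool:
        roles = self.assignment.hbond_role
        el_i = self.model.atoms[i].element
        el_j = self.model.atoms[j].element
        if el_i == "H" and el_j == "H":
            return False
        if el_i == "H" or el_j == "H":
            h, other = (i, j) if el_i == "H" else (j, i)
            donor = self.parent_of.get(h)
            if donor is None or self.model.atoms[donor].element not in ("N", "O", "S"):
                return False
            if roles[donor] not in ("donor", "both") or roles[other] not in ("acceptor", "both"):
                return False
            return self._geometry_ok(donor, h, other, max_ha, min_angle)
        for donor, acceptor in ((i, j), (j, i)):
            if roles[donor] in ("donor", "both") and roles[acceptor] in ("acceptor", "both"):
                for h in self.h_of.get(donor, []):
                    if self._geometry_ok(donor, h, acceptor, max_ha, min_angle):
                        return True
        return False


def _classify(klass_i: str, klass_j: str, a_i: float, a_j: float,
              is_hbond: bool) -> str:
    if is_hbond:
        return "hydrogen-bond"
    pair = {klass_i, klass_j}
    if pair == {"acid", "base"}:
        return "electrostatic-favorable"
    if pair == {"acid"} or pair == {"base"}:
        return "electrostatic-unfavorable"
    if a_i > 0 and a_j > 0:
        return "hydrophobic"
    if a_i * a_j < 0:
        return "desolvation"
    return "electrostatic-favorable"


def _score_pair(model: StructureModel, i: int, j: int,
                assignment: HydropathyAssignment, params: HydropathyParams,
                hb: _HBondGeometry, r: float | None = None) -> InteractionRecord:
    if r is None:
        r = float(np.linalg.norm(model.atoms[i].coords - model.atoms[j].coords))
    a_i, a_j = assignment.a[i], assignment.a[j]
    raw = assignment.sasa[i] * a_i * assignment.sasa[j] * a_j * float(params.decay(r))
    klass = _classify(assignment.polarity_class[i], assignment.polarity_class[j],
                      a_i, a_j,
                      hb.is_hbond(i, j, params.hbond_h_acceptor_max,
                                  params.hbond_angle_min))
    b = -abs(raw) if klass == "electrostatic-unfavorable" else raw
    ai = model.atoms[i]
    aj = model.atoms[j]
    return InteractionRecord(i=i, j=j,
                             atom_i=(ai.chain, ai.res_seq, ai.name),
                             atom_j=(aj.chain, aj.res_seq, aj.name),
                             r_ij=r, b_ij=b, klass=klass)


def pair_score(model: StructureModel, i: int, j: int,
               assignment: HydropathyAssignment, params: HydropathyParams,
               excluded: set[tuple[int, int]] | None = None) -> InteractionRecord:
    """Score one admissible atom pair; raises on an excluded pair."""
    if i == j:
        raise ValueError("cannot score an atom against itself")
    if excluded is None:
        excluded = model.bonded_within(params.exclusion_bond_depth)
    key = (min(i, j), max(i, j))
    if key in excluded:
        raise ValueError(f"pair {key} is covalently coupled "
                         f"(bond-graph distance <= {params.exclusion_bond_depth})")
    r = float(np.linalg.norm(model.atoms[i].coords - model.atoms[j].coords))
    if r > params.cutoff:
        raise ValueError(f"pair {key} beyond the {params.cutoff} A cutoff")
    hb = _HBondGeometry(model, assignment)
    return _score_pair(model, i, j, assignment, params, hb, r)


# --------------------------------------------------------------------------
# totals

@dataclass
class HintScoreTable:
    total_B: float
    components: dict[str, float]
    per_residue: dict[tuple[str, int], dict[str, float]]
    records: list[InteractionRecord] = field(repr=False, default_factory=list)


def admissible_pairs(model: StructureModel,
                     params: HydropathyParams) -> list[tuple[int, int, float]]:
    """All (i, j, r) with i < j, r <= cutoff and bond-graph distance > depth."""
    excluded = model.bonded_within(params.exclusion_bond_depth)
    coords = model.coords
    tree = cKDTree(coords)
    out = []
    for i, j in sorted(tree.query_pairs(params.cutoff)):
        if (i, j) in excluded:
            continue
        out.append((i, j, float(np.linalg.norm(coords[i] - coords[j]))))
    return out


def hint_total(model: StructureModel, params: HydropathyParams,
               assignment: HydropathyAssignment | None = None,
               report_threshold: float = 0.0) -> HintScoreTable:
    """Score all admissible pairs once (i < j) and aggregate.

    Per-residue totals attribute each b_ij half to each partner residue.
    ``total_B`` is computed as the sum of the class components so the
    component-closure invariant holds exactly.
    """
    if assignment is None:
        assignment = assign_hydropathy(model, params)
    hb = _HBondGeometry(model, assignment)
    components = {k: 0.0 for k in INTERACTION_CLASSES}
    per_residue: dict[tuple[str, int], dict[str, float]] = {}
    records: list[InteractionRecord] = []
    for i, j, r in admissible_pairs(model, params):
        rec = _score_pair(model, i, j, assignment, params, hb, r)
        components[rec.klass] += rec.b_ij
        for idx in (i, j):
            key = model.atoms[idx].residue_key
            slot = per_residue.setdefault(
                key, {"total": 0.0, **{k: 0.0 for k in INTERACTION_CLASSES}})
            slot["total"] += 0.5 * rec.b_ij
            slot[rec.klass] += 0.5 * rec.b_ij
        if abs(rec.b_ij) >= report_threshold:
            records.append(rec)
    return HintScoreTable(total_B=sum(components.values()),
                          components=components,
                          per_residue=per_residue,
                          records=records)


def score_trajectory(traj: Trajectory, params: HydropathyParams,
                     stride: int = 1, add_hydrogens: bool = True,
                     ) -> tuple[list[HintScoreTable], dict]:
    """Score every stride-th frame; returns tables plus a mean +/- SD summary
    (the across-frames option for error bars on the score decomposition).
    Semi-essential hydrogens are rebuilt per frame unless already present."""
    from .hydrogens import add_semi_essential_hydrogens
    tables = []
    for f in range(0, traj.n_frames, stride):
        model = traj.frame_model(f)
        if add_hydrogens:
            model = add_semi_essential_hydrogens(model)
        tables.append(hint_total(model, params))
    totals = np.array([t.total_B for t in tables])
    summary = {"total_B_mean": float(totals.mean()),
               "total_B_sd": float(totals.std(ddof=1)) if len(totals) > 1 else 0.0}
    for k in INTERACTION_CLASSES:
        vals = np.array([t.components[k] for t in tables])
        summary[f"{k}_mean"] = float(vals.mean())
        summary[f"{k}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return tables, summary


# --------------------------------------------------------------------------
# per-residue interaction report

@dataclass
class PartnerInteraction:
    partner: tuple[str, int, str]          # chain, res_seq, res_name
    total: float
    components: dict[str, float]
    records: list[InteractionRecord] = field(repr=False, default_factory=list)


def sidechain_atom_indices(model: StructureModel, chain: str, res_seq: int) -> set[int]:
    """Indices of the residue's side-chain heavy atoms and their hydrogens."""
    idx = model.residue_atom_indices(chain, res_seq)
    heavy = {i for i in idx if model.atoms[i].element != "H"
             and model.atoms[i].name not in BACKBONE_SET}
    hydrogens = set()
    for i, j in model.covalent_bonds:
        for h, p in ((i, j), (j, i)):
            if model.atoms[h].element == "H" and p in heavy:
                hydrogens.add(h)
    return heavy | hydrogens


def residue_interactions(model: StructureModel, params: HydropathyParams,
                         chain: str, res_seq: int,
                         assignment: HydropathyAssignment | None = None,
                         table: HintScoreTable | None = None) -> list[PartnerInteraction]:
    """Interactions of one residue's side chain, grouped by partner residue
    and sorted by |total| (the per-position interaction report)."""
    model.residue_name(chain, res_seq)  # raises on unknown residue
    side = sidechain_atom_indices(model, chain, res_seq)
    if not side:
        return []
    if table is None:
        table = hint_total(model, params, assignment=assignment,
                           report_threshold=0.0)
    groups: dict[tuple[str, int], PartnerInteraction] = {}
    for rec in table.records:
        in_i = rec.i in side
        in_j = rec.j in side
        if not (in_i or in_j):
            continue
        other = rec.j if in_i else rec.i
        partner_key = model.atoms[other].residue_key
        if partner_key == (chain, res_seq):
            continue
        g = groups.get(partner_key)
        if g is None:
            g = PartnerInteraction(
                partner=(partner_key[0], partner_key[1],
                         model.residue_name(*partner_key)),
                total=0.0, components={k: 0.0 for k in INTERACTION_CLASSES})
            groups[partner_key] = g
        g.total += rec.b_ij
        g.components[rec.klass] += rec.b_ij
        g.records.append(rec)
    return sorted(groups.values(), key=lambda g: abs(g.total), reverse=True)
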