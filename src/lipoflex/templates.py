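"""Residue topology templates for the 20 standard amino acids.

Everything downstream -- covalent-bond derivation, semi-essential hydrogen
placement, the point mutator and the hydropathy parameter table -- is driven
by these tables rather than by CONECT records, so plain ATOM-only PDB files
are sufficient input.
"""

from __future__ import annotations

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

WATER_RESIDUES = frozenset({"HOH", "WAT", "DOD", "H2O"})

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Heavy-atom bonds within each side chain.  Backbone bonds (N-CA, CA-C, C-O,
# C-OXT) and the inter-residue peptide bond are added generically.
SIDECHAIN_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"), ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")
BACKBONE_BONDS = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]

# sp2 / aromatic side-chain carbons (the backbone carbonyl C is sp2 in every
# residue and is handled generically).
SP2_CARBONS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"CZ"}),
    "ASN": frozenset({"CG"}),
    "ASP": frozenset({"CG"}),
    "GLN": frozenset({"CD"}),
    "GLU": frozenset({"CD"}),
    "HIS": frozenset({"CG", "CD2", "CE1"}),
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
}

# Planar (sp2) nitrogens: hydrogens on these are placed in-plane.  The
# backbone amide N is planar in every residue.
SP2_NITROGENS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "TRP": frozenset({"NE1"}),
}

# Oxygens that never carry hydrogens at neutral pH: carbonyls plus the
# deprotonated carboxylates of Asp/Glu and the C-terminal carboxylate.
NO_H_OXYGENS: dict[str, frozenset[str]] = {
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

# Neutral-pH protonation overrides keyed by (res_name, atom_name):
# explicit hydrogen counts where the valence rule is wrong.
H_COUNT_OVERRIDES: dict[tuple[str, str], int] = {
    ("HIS", "ND1"): 0,   # neutral epsilon tautomer: H sits on NE2
    ("LYS", "NZ"): 3,    # protonated ammonium
}

VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}

# van der Waals radii for SASA (A)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

# ideal hydrogen bond lengths by parent element (A)
H_BOND_LENGTHS = {"N": 1.01, "O": 0.96, "S": 1.34, "C": 1.09}


def sidechain_atom_names(res_name: str) -> set[str]:
    """Heavy side-chain atom names of a standard residue (excludes backbone)."""
    names: set[str] = set()
    for a, b in SIDECHAIN_BONDS[res_name]:
        names.update((a, b))
    names.difference_update(BACKBONE_ATOMS)
    return names


def heavy_atom_names(res_name: str) -> set[str]:
    return set(BACKBONE_ATOMS) | sidechain_atom_names(res_name)


def element_of(res_name: str, atom_name: str) -> str:
    """Element of a template atom, inferred from the PDB atom name."""
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def is_sp2(res_name: str, atom_name: str) -> bool:
    if atom_name == "C":
        return True
    if atom_name in SP2_CARBONS.get(res_name, frozenset()):
        return True
    if atom_name == "N" or atom_name in SP2_NITROGENS.get(res_name, frozenset()):
        return True
    return False


def is_semi_essential_parent(res_name: str, atom_name: str, element: str,
                             neighbor_elements: list[str]) -> bool:
    """Does this heavy atom carry hydrogens of the semi-essential set?

    The set comprises polar hydrogens (on N/O/S), hydrogens on unsaturated
    (sp2/aromatic) carbons, and hydrogens on carbons alpha to a heteroatom.
    """
    if element in ("N", "O", "S"):
        return True
    if element == "C":
        if atom_name != "C" and is_sp2(res_name, atom_name):
            return True
        return any(e in ("N", "O", "S") for e in neighbor_elements)
    return False


def template_heavy_neighbors(res_name: str, atom_name: str,
                             midchain: bool = True) -> list[str]:
    """Heavy neighbours of a template atom (mid-chain peptide context)."""
    nbrs = []
    for a, b in BACKBONE_BONDS + SIDECHAIN_BONDS[res_name]:
        if a == atom_name and (b != "OXT"):
            nbrs.append(b)
        elif b == atom_name and (a != "OXT"):
            nbrs.append(a)
    if midchain:
        if atom_name == "N":
            nbrs.append("C")   # preceding residue's carbonyl C
        elif atom_name == "C":
            nbrs.append("N")   # next residue's amide N
    return nbrs


def hydrogen_name(parent_name: str, k: int, n: int) -> str:
    """Systematic name for the k-th (0-based) of n hydrogens on a parent atom."""
    base = "H" + parent_name[1:]
    return base if n == 1 else f"{base}{k + 1}"


def semi_essential_hydrogen_names(res_name: str) -> list[tuple[str, str]]:
    """(hydrogen name, parent heavy atom name) pairs for a mid-chain residue."""
    out: list[tuple[str, str]] = []
    for atom in sorted(heavy_atom_names(res_name)):
        element = element_of(res_name, atom)
        nbrs = template_heavy_neighbors(res_name, atom)
        n_h = hydrogen_count(res_name, atom, element, len(nbrs))
        if n_h == 0:
            continue
        nbr_elements = [element_of(res_name, n) for n in nbrs]
        if not is_semi_essential_parent(res_name, atom, element, nbr_elements):
            continue
        for k in range(n_h):
            out.append((hydrogen_name(atom, k, n_h), atom))
    return out


def hydrogen_count(res_name: str, atom_name: str, element: str, heavy_degree: int) -> int:
    """Number of hydrogens carried by a heavy atom, given its realised covalent
    degree (so disulfide-bonded Cys SG and mid-chain Pro N come out to zero
    without special-casing)."""
    if element not in VALENCE:
        return 0
    override = H_COUNT_OVERRIDES.get((res_name, atom_name))
    if override is not None:
        return override
    if element == "O":
        if atom_name in ("O", "OXT"):
            return 0
        if atom_name in NO_H_OXYGENS.get(res_name, frozenset()):
            return 0
        return max(0, 2 - heavy_degree)
    cap = VALENCE[element]
    if element == "C" and is_sp2(res_name, atom_name):
        cap = 3
    return max(0, cap - heavy_degree)
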