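"""In-silico single-point mutagenesis by side-chain truncation/atom swap.

Mutations are restricted to targets whose side chain is an atom subset of
the source side chain (after the defined element swaps), so the result is
deterministic and needs no rotamer search: Y->F, Y->A, C->S, C->A and any
X->A / X->G satisfy the rule.  Coordinates of atoms that are neither deleted
nor rescaled are left bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import templates as T
from .structure import Atom, StructureModel


class UnsupportedMutationError(ValueError):
    pass


# (wt three-letter, target three-letter) -> {source atom: (new name, new
# element, anchor atom, new bond length in A)}
_ATOM_SWAPS: dict[tuple[str, str], dict[str, tuple[str, str, str, float]]] = {
    ("CYS", "SER"): {"SG": ("OG", "O", "CB", 1.41)},
}


@dataclass(frozen=True)
class MutationSpec:
    """A single-point mutation, e.g. ``MutationSpec("A", 120, "Y", "F")``."""

    chain: str
    res_seq: int
    wt: str
    target: str

    def __post_init__(self):
        for code in (self.wt, self.target):
            if code not in T.ONE_TO_THREE:
                raise ValueError(f"unknown one-letter residue code {code!r}")
        if self.wt == self.target:
            raise ValueError("mutation target equals the wild-type residue")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse ``CHAIN:SEQ:WT>TARGET`` (e.g. ``A:120:Y>F``)."""
        try:
            chain, seq, change = text.split(":")
            wt, target = change.split(">")
            return cls(chain=chain, res_seq=int(seq), wt=wt.upper(),
                       target=target.upper())
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"cannot parse mutation spec {text!r}; "
                             f"expected CHAIN:SEQ:WT>TARGET") from exc

    @property
    def label(self) -> str:
        return f"{self.wt}{self.res_seq}{self.target}"


def apply_mutation(model: StructureModel, spec: MutationSpec) -> StructureModel:
    """Return a new model with the mutation applied.

    The target side chain must be an atom subset of the source side chain
    after the allowed element swaps; surplus side-chain atoms are deleted,
    swapped atoms are renamed and their bond to the anchor rescaled to the
    ideal length along the existing direction, backbone atoms are untouched
    and every other residue is copied bit-identically.
    """
    wt3 = T.ONE_TO_THREE[spec.wt]
    tgt3 = T.ONE_TO_THREE[spec.target]
    actual = model.residue_name(spec.chain, spec.res_seq)
    if actual != wt3:
        raise ValueError(f"residue {spec.chain}:{spec.res_seq} is {actual}, "
                         f"not {wt3} as the mutation spec claims")

    swaps = _ATOM_SWAPS.get((wt3, tgt3), {})
    source_names = {a.name for a in model.atoms
                    if a.residue_key == (spec.chain, spec.res_seq)
                    and a.element != "H"}
    renamed = {old: new[0] for old, new in swaps.items()}
    available = {renamed.get(n, n) for n in source_names}
    target_sidechain = T.sidechain_atom_names(tgt3)
    missing = target_sidechain - available
    if missing:
        raise UnsupportedMutationError(
            f"{wt3}->{tgt3} at {spec.chain}:{spec.res_seq} is not a "
            f"subset-rule mutation (target atoms {sorted(missing)} have no "
            f"source counterpart); use an external rotamer tool for this one")

    keep_names = set(T.BACKBONE_ATOMS) | {"OXT"} | {
        n for n in source_names
        if renamed.get(n, n) in target_sidechain or n in T.BACKBONE_ATOMS or n == "OXT"
    }

    new_atoms: list[Atom] = []
    for a in model.atoms:
        if a.residue_key != (spec.chain, spec.res_seq):
            new_atoms.append(replace(a, coords=a.coords.copy()))
            continue
        if a.element == "H":
            continue  # hydrogens are rebuilt downstream anyway
        if a.name not in keep_names:
            continue
        if a.name in swaps:
            new_name, new_element, anchor, length = swaps[a.name]
            anchor_idx = model.atom_index(spec.chain, spec.res_seq, anchor)
            anchor_pos = model.atoms[anchor_idx].coords
            direction = a.coords - anchor_pos
            norm = np.linalg.norm(direction)
            if norm < 1e-6:
                raise ValueError(f"degenerate {anchor}-{a.name} bond at "
                                 f"{spec.chain}:{spec.res_seq}")
            new_coords = anchor_pos + direction / norm * length
            new_atoms.append(replace(a, name=new_name, element=new_element,
                                     res_name=tgt3, coords=new_coords))
        else:
            new_atoms.append(replace(a, res_name=tgt3, coords=a.coords.copy()))

    out = StructureModel(new_atoms)
    out.segments = {k: list(v) for k, v in model.segments.items()}
    out.validate()
    return out
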