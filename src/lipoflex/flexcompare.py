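"""Wild-type vs mutant flexibility differencing with epitope annotation.

A residue is flagged as significantly more/less flexible when its RMSF
changes by at least 0.7 A (inclusive threshold); residues with wild-type
RMSF >= 2.5 A are additionally marked as intrinsically high-flexibility.
The shipped epitope annotation is the published Discotope prediction for
the mouse major urinary protein allergen (epitopes I-III).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .trajmetrics import FlexibilityProfile

DEFAULT_DELTA_THRESHOLD = 0.7   # A
DEFAULT_HIGH_FLEX = 2.5         # A

#: Conformational epitope residue sets (residue number -> expected name).
DEFAULT_EPITOPES: dict[str, dict[int, str]] = {
    "I": {1: "GLU", 7: "GLY", 8: "ARG", 9: "ASN", 11: "ASN", 13: "GLU"},
    "II": {30: "GLU", 34: "ASP", 35: "ASN", 61: "ASP"},
    "III": {110: "ASP", 111: "GLY", 112: "GLU"},
}


@dataclass
class FlexDelta:
    residue: tuple[str, int]
    rmsf_wt: float
    rmsf_mut: float
    delta: float                 # mut - wt, A
    flag: str                    # increased | decreased | unchanged
    epitope: str = "none"        # I | II | III | none
    high_flex_wt: bool = False


def delta_rmsf(wt: FlexibilityProfile, mut: FlexibilityProfile,
               threshold: float = DEFAULT_DELTA_THRESHOLD,
               high_flex: float = DEFAULT_HIGH_FLEX) -> list[FlexDelta]:
    """Per-residue RMSF differences with inclusive significance flags.

    Profiles must cover identical residue keys (the mutated position is
    matched by residue number, its name change notwithstanding).
    """
    if threshold <= 0 or high_flex <= 0:
        raise ValueError("thresholds must be positive")
    keys_wt = set(wt.rmsf)
    keys_mut = set(mut.rmsf)
    if keys_wt != keys_mut:
        only_wt = sorted(keys_wt - keys_mut)
        only_mut = sorted(keys_mut - keys_wt)
        raise ValueError(f"profiles cover different residues "
                         f"(only in wt: {only_wt}; only in mutant: {only_mut})")
    out = []
    for key in sorted(keys_wt):
        d = mut.rmsf[key] - wt.rmsf[key]
        if d >= threshold:
            flag = "increased"
        elif d <= -threshold:
            flag = "decreased"
        else:
            flag = "unchanged"
        out.append(FlexDelta(residue=key, rmsf_wt=wt.rmsf[key],
                             rmsf_mut=mut.rmsf[key], delta=d, flag=flag,
                             high_flex_wt=wt.rmsf[key] >= high_flex))
    return out


def annotate_epitopes(deltas: list[FlexDelta],
                      annotation: dict[str, dict[int, str]] | None = None,
                      ) -> tuple[list[FlexDelta], dict[str, dict[str, int]]]:
    """Label each delta with its epitope (if any) and summarise flag counts
    per epitope.  Annotation entries referencing absent residues produce a
    warning, not an error."""
    if annotation is None:
        annotation = DEFAULT_EPITOPES
    by_seq: dict[int, str] = {}
    for label, members in annotation.items():
        for seq in members:
            if seq in by_seq:
                raise ValueError(f"residue {seq} appears in epitopes "
                                 f"{by_seq[seq]} and {label}")
            by_seq[seq] = label
    present = {key[1] for d in deltas for key in [d.residue]}
    for seq, label in by_seq.items():
        if seq not in present:
            warnings.warn(f"epitope {label} residue {seq} absent from profile",
                          stacklevel=2)
    summary = {label: {"increased": 0, "decreased": 0, "unchanged": 0, "n": 0}
               for label in annotation}
    for d in deltas:
        label = by_seq.get(d.residue[1], "none")
        d.epitope = label
        if label != "none":
            summary[label][d.flag] += 1
            summary[label]["n"] += 1
    return deltas, summary
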