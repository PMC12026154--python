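"""End-to-end analysis pipeline: mutate -> score -> trajectory metrics ->
flexibility comparison, driven by a single validated configuration.

Outputs are deterministic for a fixed config (stable column order, fixed
float formatting, no timestamps), so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from . import trajmetrics as tm
from .flexcompare import DEFAULT_EPITOPES, annotate_epitopes, delta_rmsf
from .hint import (INTERACTION_CLASSES, hint_total, load_params,
                   residue_interactions)
from .hydrogens import add_semi_essential_hydrogens
from .mutate import MutationSpec, apply_mutation
from .structure import StructureModel, Trajectory
from .synthetic import (MotionSpec, ToySpec, make_breathing_trajectory,
                        make_harmonic_trajectory, make_toy_protein)

log = logging.getLogger("lipoflex")

SCHEMA_VERSION = 1
DEFAULT_METRICS = ("rmsd", "rmsf", "rg", "sasa", "dist", "pca")
FLOAT_FMT = "%.6f"


class ConfigError(ValueError):
    """Invalid run configuration (reported before any computation)."""


@dataclass
class RunConfig:
    outdir: str
    structure: str | None = None            # wild-type PDB; None => synthetic toy
    trajectory: str | None = None           # wild-type multi-model PDB
    mutations: list[str] = dfield(default_factory=list)
    mutant_trajectories: dict[str, str] = dfield(default_factory=dict)
    params_path: str | None = None
    metrics: list[str] = dfield(default_factory=lambda: list(DEFAULT_METRICS))
    delta_rmsf_threshold: float = 0.7       # A
    high_flex_threshold: float = 2.5        # A
    tail_fraction: float = 0.4              # averaging window for Rg/SASA tails
    pair_spec_path: str | None = None
    epitopes: str = "default"               # default | none
    sasa_stride: int = 10
    dt: float = 1.0
    seed: int = 0
    synthetic: bool = False
    synthetic_spec: dict = dfield(default_factory=dict)
    synthetic_motion: dict = dfield(default_factory=dict)
    mutant_sigma_scale: float = 1.5
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ConfigError("config must set 'outdir'")
        return cls(**raw)

    def validate(self) -> None:
        if self.delta_rmsf_threshold <= 0 or self.high_flex_threshold <= 0:
            raise ConfigError("thresholds must be positive")
        if not (0 < self.tail_fraction <= 1):
            raise ConfigError("tail_fraction must be in (0, 1]")
        if self.structure is None and not self.synthetic:
            raise ConfigError("either 'structure' or 'synthetic: true' is required")
        if self.structure is not None and self.synthetic:
            raise ConfigError("'structure' and 'synthetic' are mutually exclusive")
        unknown = set(self.metrics) - set(DEFAULT_METRICS)
        if unknown:
            raise ConfigError(f"unknown metrics requested: {sorted(unknown)}")
        if "dist" in self.metrics and not self.synthetic and not self.pair_spec_path:
            raise ConfigError("metric 'dist' requires 'pair_spec_path' "
                              "(or a synthetic run)")
        if self.epitopes not in ("default", "none"):
            raise ConfigError("epitopes must be 'default' or 'none'")
        for m in self.mutations:
            MutationSpec.parse(m)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location and logging
        verbosity excluded, so identical analyses hash identically)."""
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("outdir", "log_level")}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def read_pair_spec(path: str | Path) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    df = pd.read_csv(path, sep="\t")
    need = {"helix_chain", "helix_seq", "barrel_chain", "barrel_seq"}
    if not need <= set(df.columns):
        raise ConfigError(f"pair spec {path} must have columns {sorted(need)}")
    return [((str(r.helix_chain), int(r.helix_seq)),
             (str(r.barrel_chain), int(r.barrel_seq)))
            for r in df.itertuples(index=False)]


def _write_profile(prof: tm.FlexibilityProfile, path: Path) -> None:
    rows = [{"chain": c, "res_seq": s, "res_name": prof.res_names.get((c, s), ""),
             "rmsf": v} for (c, s), v in sorted(prof.rmsf.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_profile(path: str | Path) -> tm.FlexibilityProfile:
    df = pd.read_csv(path, sep="\t")
    rmsf = {(str(r.chain), int(r.res_seq)): float(r.rmsf)
            for r in df.itertuples(index=False)}
    names = {(str(r.chain), int(r.res_seq)): str(getattr(r, "res_name", ""))
             for r in df.itertuples(index=False)}
    return tm.FlexibilityProfile(rmsf=rmsf, res_names=names)


def write_deltas(deltas, path: Path) -> None:
    rows = [{"chain": d.residue[0], "res_seq": d.residue[1],
             "rmsf_wt": d.rmsf_wt, "rmsf_mut": d.rmsf_mut, "delta": d.delta,
             "flag": d.flag, "epitope": d.epitope,
             "high_flex_wt": d.high_flex_wt} for d in deltas]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_score_table(table, path: Path) -> None:
    rows = []
    for (chain, seq), comp in sorted(table.per_residue.items()):
        row = {"chain": chain, "res_seq": seq, "total": comp["total"]}
        row.update({k: comp[k] for k in INTERACTION_CLASSES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_interaction_report(partners, path: Path) -> None:
    rows = []
    for g in partners:
        row = {"partner_chain": g.partner[0], "partner_seq": g.partner[1],
               "partner_name": g.partner[2], "total": g.total}
        row.update({k: g.components[k] for k in INTERACTION_CLASSES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _tail(series: np.ndarray, fraction: float) -> np.ndarray:
    n = max(1, int(round(len(series) * fraction)))
    return series[-n:]


def _metrics_for(label: str, traj: Trajectory, cfg: RunConfig,
                 pair_spec, outdir: Path) -> dict:
    summary: dict = {}
    if "rmsd" in cfg.metrics:
        series = tm.rmsd_series(traj)
        pd.DataFrame({"frame": np.arange(len(series)), "rmsd": series}).to_csv(
            outdir / f"{label}_rmsd.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        summary["rmsd_mean"] = float(series.mean())
        summary["rmsd_sd"] = float(series.std(ddof=1))
    prof = None
    if "rmsf" in cfg.metrics:
        prof = tm.rmsf_profile(traj)
        _write_profile(prof, outdir / f"{label}_rmsf.tsv")
    if "rg" in cfg.metrics:
        rg = tm.gyration_series(traj)
        pd.DataFrame({"frame": np.arange(len(rg)), "rg": rg}).to_csv(
            outdir / f"{label}_rg.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        tail = _tail(rg, cfg.tail_fraction)
        summary["rg_tail_mean"] = float(tail.mean())
        summary["rg_tail_sd"] = float(tail.std(ddof=1)) if len(tail) > 1 else 0.0
    if "sasa" in cfg.metrics:
        s = tm.sasa_series(traj, stride=cfg.sasa_stride)
        pd.DataFrame({"frame": np.arange(0, traj.n_frames, cfg.sasa_stride),
                      "sasa": s}).to_csv(
            outdir / f"{label}_sasa.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        tail = _tail(s, cfg.tail_fraction)
        summary["sasa_tail_mean"] = float(tail.mean())
        summary["sasa_tail_sd"] = float(tail.std(ddof=1)) if len(tail) > 1 else 0.0
    if "dist" in cfg.metrics and pair_spec:
        hb = tm.helix_barrel_distance(traj, pair_spec)
        pd.DataFrame({"frame": np.arange(len(hb.d)), "distance": hb.d}).to_csv(
            outdir / f"{label}_dist.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        summary["D_max"] = hb.D_max
        summary["D_ave"] = hb.D_ave
        summary["D_sd"] = hb.D_sd
    if "pca" in cfg.metrics:
        pca = tm.pca_essential(traj)
        pd.DataFrame({"frame": np.arange(pca.projections.shape[0]),
                      "pc1": pca.projections[:, 0],
                      "pc2": pca.projections[:, 1] if pca.projections.shape[1] > 1
                      else np.zeros(pca.projections.shape[0])}).to_csv(
            outdir / f"{label}_pca.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
        summary["pc_ranges"] = [list(r) for r in pca.ranges]
        summary["pc_explained_variance"] = [float(x) for x in pca.explained_variance]
    return summary, prof


def _synthetic_wt(cfg: RunConfig) -> tuple[StructureModel, Trajectory, list]:
    spec_kwargs = dict(cfg.synthetic_spec)
    spec_kwargs.setdefault("seed", cfg.seed)
    spec = ToySpec(**spec_kwargs)
    model = make_toy_protein(spec)
    motion_kwargs = dict(cfg.synthetic_motion)
    motion_kwargs.setdefault("seed", cfg.seed)
    motion = MotionSpec(**motion_kwargs)
    traj = make_harmonic_trajectory(model, motion, dt=cfg.dt)
    breathing = make_breathing_trajectory(model, motion, dt=cfg.dt)
    # splice the breathing displacement of the helix onto the harmonic noise
    # so one trajectory carries both ground-truth motions
    helix_res = set(model.segments["helix"])
    mask = np.array([a.residue_key in helix_res for a in model.atoms])
    nf = min(traj.n_frames, breathing.trajectory.n_frames)
    frames = traj.frames[:nf].copy()
    frames[:, mask, :] += (breathing.trajectory.frames[:nf, mask, :]
                           - model.coords[mask][None])
    return model, Trajectory(model, frames, dt=cfg.dt), breathing.pair_spec


def _mutant_trajectory(cfg: RunConfig, model: StructureModel,
                       spec: MutationSpec, mut_model: StructureModel) -> Trajectory:
    """Synthetic mutant trajectory: same harmonic conditions, with the
    fluctuation amplitude at the mutated residue scaled (a demo emulation of
    a mutation-induced flexibility change)."""
    motion_kwargs = dict(cfg.synthetic_motion)
    motion_kwargs.setdefault("seed", cfg.seed)
    motion = MotionSpec(**motion_kwargs)
    sigmas = motion.sigma_vector(len(mut_model.residues)).copy()
    for k, (c, s, _) in enumerate(mut_model.residues):
        if (c, s) == (spec.chain, spec.res_seq):
            sigmas[k] *= cfg.mutant_sigma_scale
    motion = MotionSpec(sigmas=sigmas,
                        breathing_amplitude=motion.breathing_amplitude,
                        breathing_period=motion.breathing_period,
                        n_frames=motion.n_frames, jitter=motion.jitter,
                        seed=motion.seed + 1)
    return make_harmonic_trajectory(mut_model, motion, dt=cfg.dt)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured analysis; returns the bundle summary dict.

    For each protein (wild type and every mutant) the bundle contains the
    mutated PDB, per-residue score table, interaction report at the mutated
    position, requested metric series as TSV, FlexDelta tables against the
    wild type, and one JSON summary; plus a run log with the config hash.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    params = load_params(cfg.params_path)
    mut_specs = [MutationSpec.parse(m) for m in cfg.mutations]

    stage = "input"
    try:
        pair_spec = None
        if cfg.synthetic:
            wt_model, wt_traj, pair_spec = _synthetic_wt(cfg)
        else:
            wt_model = lio.read_pdb(cfg.structure)
            wt_traj = (lio.read_multimodel_trajectory(cfg.trajectory, dt=cfg.dt)
                       if cfg.trajectory else None)
        if cfg.pair_spec_path:
            pair_spec = read_pair_spec(cfg.pair_spec_path)

        proteins: list[tuple[str, StructureModel, Trajectory | None,
                             MutationSpec | None]] = [("wt", wt_model, wt_traj, None)]
        stage = "mutate"
        for spec in mut_specs:
            mut = apply_mutation(wt_model, spec)
            lio.write_pdb(mut, outdir / f"{spec.label.lower()}.pdb")
            if cfg.synthetic:
                mtraj = _mutant_trajectory(cfg, wt_model, spec, mut)
            elif spec.label in cfg.mutant_trajectories:
                mtraj = lio.read_multimodel_trajectory(
                    cfg.mutant_trajectories[spec.label], dt=cfg.dt)
            else:
                mtraj = None
            proteins.append((spec.label.lower(), mut, mtraj, spec))

        bundle: dict = {"schema_version": SCHEMA_VERSION,
                        "config_hash": cfg.config_hash(),
                        "seed": cfg.seed, "proteins": {}}
        wt_profile = None
        for label, model, traj, spec in proteins:
            stage = f"score:{label}"
            scored = add_semi_essential_hydrogens(model)
            table = hint_total(scored, params)
            write_score_table(table, outdir / f"{label}_scores.tsv")
            summary = {"total_B": table.total_B,
                       "components": {k: table.components[k]
                                      for k in INTERACTION_CLASSES}}
            report_pos = [(s.chain, s.res_seq) for s in mut_specs]
            for chain, seq in report_pos:
                partners = residue_interactions(scored, params, chain, seq,
                                                table=table)
                write_interaction_report(
                    partners, outdir / f"{label}_interactions_{chain}{seq}.tsv")
            if traj is not None:
                stage = f"metrics:{label}"
                msum, prof = _metrics_for(label, traj, cfg, pair_spec, outdir)
                summary.update(msum)
                if label == "wt":
                    wt_profile = prof
                elif prof is not None and wt_profile is not None:
                    stage = f"compare:{label}"
                    deltas = delta_rmsf(wt_profile, prof,
                                        threshold=cfg.delta_rmsf_threshold,
                                        high_flex=cfg.high_flex_threshold)
                    annotation = (DEFAULT_EPITOPES if cfg.epitopes == "default"
                                  else {})
                    import warnings as _w
                    with _w.catch_warnings():
                        _w.simplefilter("ignore")
                        deltas, epi_summary = annotate_epitopes(deltas, annotation)
                    write_deltas(deltas, outdir / f"{label}_delta_rmsf.tsv")
                    summary["flagged_residues"] = sum(
                        d.flag != "unchanged" for d in deltas)
                    summary["epitope_summary"] = epi_summary
            bundle["proteins"][label] = summary
            with open(outdir / f"{label}_summary.json", "w") as fh:
                json.dump({"schema_version": SCHEMA_VERSION, **summary},
                          fh, indent=2, sort_keys=True)
        with open(outdir / "run.log", "w") as fh:
            fh.write(f"config_hash={cfg.config_hash()}\nseed={cfg.seed}\n"
                     f"proteins={[p[0] for p in proteins]}\n")
        return bundle
    except (ConfigError, KeyboardInterrupt):
        raise
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
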