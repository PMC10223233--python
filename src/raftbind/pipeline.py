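"""Configuration-driven orchestration of the analysis stages.

A run config (YAML or dict) names the inputs, the enabled stages and every
threshold; :func:`run_pipeline` executes the stages in dependency order
(domains -> shells -> binding -> structure -> folding) on a synthetic or
file-based system and writes TSV/JSON outputs plus a provenance manifest.
"""
from __future__ import annotations

import itertools
import json
import logging
import os
import time as _time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binding import (
    aggregate_spectra,
    detect_binding_time,
    hydropathy_profile,
    mindist_timeseries,
    residue_mindist_spectrum,
    sequence_charge,
)
from .config import (
    BINDING_D_BOUND,
    BINDING_DWELL_CG,
    BINDING_OCCUPANCY,
    CLUSTER_LINKAGE_CUTOFF,
    CONTACT_CUTOFF,
    DOMAIN_PROXIMITY_THRESHOLD,
    MoleculeType,
)
from .core import Trajectory, window_select
from .errors import ConfigError
from .folding import folding_kinetics, regroup_ss
from .geometry import AtomSelection
from .io import write_table
from .nanodomains import assign_leaflets, domain_composition_timeseries
from .shells import ShellScheme, shell_composition, shells_over_trajectory
from .structure import area_per_lipid, bilayer_thickness, chain_order_parameter
from .synthetic import SyntheticSpec, generate_binding_trajectory, generate_ss_matrix, uniform_transition_matrix

log = logging.getLogger("raftbind")


@dataclass
class ExperimentGrid:
    """The study's experiment axes: oligomer size x membrane x replicate."""

    oligomer_sizes: tuple = (1, 2, 4)
    membranes: tuple = ("CO", "PS", "GM")
    replicates: tuple = (1, 2, 3)


def expand_experiment_grid(grid: ExperimentGrid) -> list[dict]:
    """Cartesian product in deterministic lexicographic order."""
    for name in ("oligomer_sizes", "membranes", "replicates"):
        if not getattr(grid, name):
            raise ConfigError(f"experiment-grid axis {name} is empty")
    return [
        {"n": n, "raft": m, "replicate": r}
        for n, m, r in itertools.product(
            grid.oligomer_sizes, grid.membranes, grid.replicates
        )
    ]


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults = the study's parameters)."""

    outdir: str = "raftbind_out"
    seed: int = 1
    stages: tuple = ("domains", "shells", "binding", "structure", "folding")
    domain_threshold: float = DOMAIN_PROXIMITY_THRESHOLD
    linkage_cutoff: float = CLUSTER_LINKAGE_CUTOFF
    contact_cutoff: float = CONTACT_CUTOFF
    shell_bins: tuple = ShellScheme().bins
    d_bound: float = BINDING_D_BOUND
    dwell: float = BINDING_DWELL_CG
    occupancy: float = BINDING_OCCUPANCY
    window: str | None = None
    synthetic: dict = field(default_factory=dict)
    ss_matrix: str | None = None       # path to a secondary-structure table
    ss_dialect: str = "TSV"
    quiet: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "shell_bins" in data:
            data["shell_bins"] = tuple(tuple(b) for b in data["shell_bins"])
        return cls(**data)

    def validate(self) -> None:
        for name in ("domain_threshold", "linkage_cutoff", "contact_cutoff", "d_bound"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")


def _stage(cfg: RunConfig, name: str):
    enabled = name in cfg.stages
    if not cfg.quiet:
        log.info("stage %-10s %s", name, "running" if enabled else "skipped")
    return enabled


def run_pipeline(cfg: RunConfig, traj: Trajectory | None = None) -> dict:
    """Execute the enabled stages and write all outputs + a manifest.

    If no trajectory is supplied, a synthetic binding trajectory is
    generated from ``cfg.synthetic`` (seeded by ``cfg.seed``).  Returns a
    dict of the produced file paths and key results.
    """
    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    t_start = _time.time()
    if traj is None:
        spec = SyntheticSpec(**cfg.synthetic)
        traj, gt = generate_binding_trajectory(spec, cfg.seed)
    else:
        spec, gt = None, None

    topo = traj.topology
    report: dict = {"outputs": {}, "results": {}}
    params = {
        "seed": cfg.seed,
        "domain_threshold": cfg.domain_threshold,
        "contact_cutoff": cfg.contact_cutoff,
        "d_bound": cfg.d_bound,
        "dwell": cfg.dwell,
        "occupancy": cfg.occupancy,
        "window": cfg.window,
    }

    protein_idx = topo.protein_indices()
    protein = AtomSelection("protein", protein_idx) if protein_idx.size else None
    leaflets = assign_leaflets(traj.frames[-1], topo)

    if _stage(cfg, "domains"):
        df, means = domain_composition_timeseries(
            traj, cfg.window, cfg.domain_threshold, cfg.linkage_cutoff
        )
        p = os.path.join(cfg.outdir, "domain_composition.tsv")
        write_table(df, p, {**params, "stage": "domains"})
        report["outputs"]["domains"] = p
        report["results"]["domain_means"] = means

    assignments = None
    if _stage(cfg, "shells") and protein is not None:
        scheme = ShellScheme(bins=cfg.shell_bins)
        assignments = shells_over_trajectory(traj, protein, scheme, cfg.window)
        comp = shell_composition(assignments, topo)
        p = os.path.join(cfg.outdir, "shell_composition.tsv")
        write_table(comp, p, {**params, "stage": "shells", "bins": cfg.shell_bins})
        report["outputs"]["shells"] = p

    if _stage(cfg, "binding") and protein is not None:
        partner_types = [
            t for t in (MoleculeType.DPPC, MoleculeType.DLPC, MoleculeType.CHOL,
                        MoleculeType.POPS, MoleculeType.GM1, MoleculeType.WATER)
            if topo.type_indices(t).size
        ]
        rows = []
        events = {}
        lipid_partners = [t for t in partner_types if t is not MoleculeType.WATER]
        for t in partner_types:
            series = mindist_timeseries(traj, protein, t, cfg.contact_cutoff)
            for tt, d, c in zip(series.times, series.d_min, series.contacts):
                rows.append({"time": tt, "partner": t.value, "d_min": d, "contacts": c})
            if t in lipid_partners:
                ev = detect_binding_time(series, cfg.d_bound, cfg.dwell, cfg.occupancy)
                events[t.value] = ev.t_bind
        p = os.path.join(cfg.outdir, "mindist_timeseries.tsv")
        write_table(pd.DataFrame(rows), p, {**params, "stage": "binding"})
        report["outputs"]["binding"] = p
        with open(os.path.join(cfg.outdir, "binding_events.json"), "w") as fh:
            json.dump(events, fh, indent=1)
        report["results"]["binding_events"] = events

        spec_partners = lipid_partners + [MoleculeType.WATER] if MoleculeType.WATER in partner_types else lipid_partners
        spectrum = residue_mindist_spectrum(traj, cfg.window, spec_partners)
        srows = []
        for pname in spectrum.partners:
            mean, sem = aggregate_spectra([spectrum], pname)
            for r in range(spectrum.n_residues):
                srows.append(
                    {"residue": r + 1, "partner": pname, "mean": mean[r], "sem": sem[r]}
                )
        p = os.path.join(cfg.outdir, "mindist_spectrum.tsv")
        write_table(pd.DataFrame(srows), p, {**params, "stage": "binding"})
        report["outputs"]["spectrum"] = p

        seqs = topo.protein_sequences
        if seqs:
            seq = next(iter(seqs.values()))
            prof = hydropathy_profile(seq)
            rec = sequence_charge(seq)
            report["results"]["net_charge"] = rec.net_charge
            report["results"]["hydropathy_peaks"] = prof.peaks

    if _stage(cfg, "structure"):
        wtraj = window_select(traj, cfg.window) if cfg.window else traj
        frame = wtraj.frames[-1]
        thick = bilayer_thickness(frame, topo, leaflets)
        apl = area_per_lipid(frame, topo, leaflets, "TOP")
        rows = [
            {"metric": "thickness", "mean": float(np.mean(list(thick.values()))), "n": len(thick)},
            {"metric": "apl", "mean": float(np.mean(list(apl.values()))), "n": len(apl)},
        ]
        for t in (MoleculeType.DPPC, MoleculeType.DLPC):
            ids = [int(m) for m in topo.lipid_molecule_ids(t)]
            if ids:
                prof = chain_order_parameter(wtraj.frames[-5:], topo, ids, t)
                for c, s in zip(prof.carbons, prof.s):
                    rows.append({"metric": f"S_{t.value}", "carbon": int(c), "mean": float(s)})
        p = os.path.join(cfg.outdir, "membrane_metrics.tsv")
        write_table(pd.DataFrame(rows), p, {**params, "stage": "structure"})
        report["outputs"]["structure"] = p

    if _stage(cfg, "folding"):
        if cfg.ss_matrix:
            from .folding import read_ss_matrix

            ss = read_ss_matrix(cfg.ss_matrix, cfg.ss_dialect)
            times = ss.times
        else:
            n_res = sum(len(s) for s in topo.protein_sequences.values()) or 37
            ss, _ = generate_ss_matrix(
                n_res, traj.n_frames, uniform_transition_matrix(), seed=cfg.seed
            )
            times = traj.times
        cats = regroup_ss(ss)
        kin = folding_kinetics(cats, times)
        p = os.path.join(cfg.outdir, "folding_kinetics.tsv")
        write_table(kin, p, {**params, "stage": "folding"})
        report["outputs"]["folding"] = p

    manifest = {
        "version": __version__,
        "parameters": params,
        "stages": list(cfg.stages),
        "shell_bins": [list(b) for b in cfg.shell_bins],
        "n_frames": traj.n_frames,
        "n_atoms": topo.n_atoms,
        "elapsed_s": round(_time.time() - t_start, 3),
        "outputs": report["outputs"],
    }
    mpath = os.path.join(cfg.outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    report["manifest"] = mpath
    return report
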