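"""Readers and writers for structures, trajectories and result tables.

File parsing is delegated to MDAnalysis; this module only maps its Universe
onto the package's typed data model (nm units, molecule-type labels,
protein chain bookkeeping) and back.  Orthorhombic boxes only.
"""
from __future__ import annotations

import os
from typing import Sequence

import MDAnalysis as mda
import numpy as np
import pandas as pd

from .config import DEFAULT_RESNAME_MAP, MoleculeType
from .core import Atom, Frame, Topology, Trajectory
from .errors import (
    LabelingError,
    OrderingError,
    ParseError,
    TopologyError,
    UnsupportedFeatureError,
)

A_PER_NM = 10.0

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "HSD": "H", "HSE": "H", "HSP": "H",
}
ONE_TO_THREE = {v: k for k, v in list(_THREE_TO_ONE.items())[:20]}


def _pdb_cryst1_box(path: str) -> np.ndarray | None:
    """CRYST1 record fallback: the multi-model PDB reader only honours
    per-model CRYST1 lines, but a single header record is common."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                vals = [float(line[6 + 9 * k : 15 + 9 * k]) for k in range(3)]
                angles = [float(line[33 + 7 * k : 40 + 7 * k]) for k in range(3)]
                return np.array(vals + angles)
            if line.startswith(("ATOM", "HETATM", "MODEL")):
                break
    return None


def _box_from_dimensions(dimensions: np.ndarray) -> np.ndarray:
    if dimensions is None:
        raise ParseError("file carries no box information")
    lx, ly, lz, alpha, beta, gamma = [float(x) for x in dimensions]
    if not (np.isclose(alpha, 90) and np.isclose(beta, 90) and np.isclose(gamma, 90)):
        raise UnsupportedFeatureError("triclinic boxes are not supported")
    return np.array([lx, ly, lz]) / A_PER_NM


def _universe_to_topology(
    u: mda.Universe,
    resname_map: dict[str, MoleculeType] | None,
    strict: bool,
) -> Topology:
    """Label residues with molecule types and assemble the typed topology.

    Each non-protein residue is one molecule; consecutive protein residues
    form a chain (a new chain starts whenever the residue numbering resets),
    and each chain is one molecule labelled A, B, C, ...
    """
    rmap = dict(DEFAULT_RESNAME_MAP)
    if resname_map:
        rmap.update(resname_map)

    atoms: list[Atom] = []
    mol_counter = 0
    chain_ordinal = -1
    chain_resid_prev: int | None = None
    chain_res_counter = 0
    sequences: dict[str, list[str]] = {}
    atom_id = 0

    for res in u.residues:
        resname = str(res.resname).strip()
        mtype = rmap.get(resname)
        if mtype is None:
            if strict:
                raise LabelingError(f"unknown residue name {resname!r}")
            mtype = MoleculeType.ION

        if mtype is MoleculeType.PROTEIN:
            resid = int(res.resid)
            if chain_resid_prev is None or resid <= chain_resid_prev:
                chain_ordinal += 1
                chain_res_counter = 0
                mol_counter += 1
            chain_resid_prev = resid
            chain_res_counter += 1
            chain_id = chr(ord("A") + chain_ordinal)
            sequences.setdefault(chain_id, []).append(_THREE_TO_ONE.get(resname, "X"))
            mol_id = mol_counter
            residue_index = chain_res_counter
        else:
            chain_resid_prev = None
            mol_counter += 1
            chain_id = None
            mol_id = mol_counter
            residue_index = 1

        for a in res.atoms:
            atom_id += 1
            atoms.append(
                Atom(
                    atom_id=atom_id,
                    atom_name=str(a.name).strip(),
                    residue_index=residue_index,
                    residue_name=resname,
                    molecule_id=mol_id,
                    molecule_type=mtype,
                    chain_id=chain_id,
                )
            )

    return Topology(atoms, protein_sequences={k: "".join(v) for k, v in sequences.items()})


def load_structure(
    path: str | os.PathLike,
    dialect: str = "GRO",
    resname_map: dict[str, MoleculeType] | None = None,
    strict: bool = False,
) -> tuple[Topology, Frame]:
    """Read a GRO or PDB file into ``(Topology, Frame)`` with nm positions."""
    dialect = dialect.upper()
    if dialect not in ("GRO", "PDB"):
        raise ParseError(f"unknown structure dialect {dialect!r}")
    try:
        u = mda.Universe(str(path), format=dialect)
    except Exception as exc:  # MDAnalysis raises many flavours
        raise ParseError(f"cannot parse {path} as {dialect}: {exc}") from exc
    topology = _universe_to_topology(u, resname_map, strict)
    dims = u.dimensions
    if dims is None and dialect == "PDB":
        dims = _pdb_cryst1_box(str(path))
    frame = Frame(
        positions=u.atoms.positions.astype(np.float64) / A_PER_NM,
        box=_box_from_dimensions(dims),
        time=0.0,
    )
    return topology, frame


def _make_universe(topology: Topology, frame: Frame) -> mda.Universe:
    n_atoms = topology.n_atoms
    # one MDAnalysis residue per (molecule, residue_index) pair
    res_keys: list[tuple[int, int]] = []
    atom_resindex = np.empty(n_atoms, dtype=np.intp)
    for i, a in enumerate(topology.atoms):
        key = (a.molecule_id, a.residue_index)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex[i] = len(res_keys) - 1
    u = mda.Universe.empty(
        n_atoms, n_residues=len(res_keys), atom_resindex=atom_resindex, trajectory=True
    )
    u.add_TopologyAttr("names", [a.atom_name for a in topology.atoms])
    resnames, resids = [], []
    seen = {}
    for a in topology.atoms:
        key = (a.molecule_id, a.residue_index)
        if key not in seen:
            seen[key] = True
            resnames.append(a.residue_name)
            resids.append(a.residue_index if a.chain_id is not None else len(resids) + 1)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.atoms.positions = frame.positions * A_PER_NM
    u.dimensions = [*(frame.box * A_PER_NM), 90.0, 90.0, 90.0]
    return u


def write_structure(topology: Topology, frame: Frame, path: str | os.PathLike) -> None:
    """Write one frame as GRO or PDB (decided by the file extension)."""
    u = _make_universe(topology, frame)
    u.atoms.write(str(path))


def write_trajectory(
    topology: Topology, frames: Sequence[Frame], path: str | os.PathLike
) -> None:
    """Write frames as a multi-model PDB (or XTC/DCD by extension)."""
    u = _make_universe(topology, frames[0])
    with mda.Writer(str(path), n_atoms=topology.n_atoms, multiframe=True) as w:
        for f in frames:
            u.atoms.positions = f.positions * A_PER_NM
            u.dimensions = [*(f.box * A_PER_NM), 90.0, 90.0, 90.0]
            w.write(u.atoms)


def _validate_multimodel_pdb(path: str) -> None:
    """Reject multi-model PDBs whose models carry unequal atom counts."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                counts.append(current or 0)
                current = None
    if current:  # trailing model without ENDMDL
        counts.append(current)
    if counts and len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts) if c != counts[0])
        raise ParseError(
            f"truncated or ragged trajectory: frame {bad} has {counts[bad]} atoms, "
            f"frame 0 has {counts[0]}"
        )


def iter_trajectory(
    path: str | os.PathLike,
    topology: Topology,
    dt: float = 1.0,
    t0: float = 0.0,
    times: Sequence[float] | None = None,
    structure: str | os.PathLike | None = None,
    resolution_tag: str = "CG",
) -> Trajectory:
    """Read a trajectory (multi-model PDB, XTC or DCD) against a topology.

    Times are ``t0 + i * dt`` in ns unless ``times`` is given explicitly
    (the common MD containers do not store reliable stamps for every
    dialect).  Frame atom counts must match the topology.
    """
    path = str(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdb":
        _validate_multimodel_pdb(path)
        u = mda.Universe(path)
    elif ext in (".xtc", ".dcd"):
        if structure is None:
            raise ParseError(f"{ext} trajectories need a structure file")
        u = mda.Universe(str(structure), path)
    else:
        raise ParseError(f"unknown trajectory format {ext!r}")

    if u.atoms.n_atoms != topology.n_atoms:
        raise TopologyError(
            f"trajectory has {u.atoms.n_atoms} atoms, topology has {topology.n_atoms}"
        )
    n_frames = len(u.trajectory)
    if times is not None:
        times = np.asarray(times, dtype=np.float64)
        if times.size != n_frames:
            raise OrderingError(f"{times.size} times for {n_frames} frames")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise OrderingError("explicit frame times are not strictly increasing")
    fallback_box = _pdb_cryst1_box(path) if ext == ".pdb" else None
    frames = []
    for i, ts in enumerate(u.trajectory):
        t = float(times[i]) if times is not None else t0 + i * dt
        dims = ts.dimensions if ts.dimensions is not None else fallback_box
        frames.append(
            Frame(
                positions=ts.positions.astype(np.float64) / A_PER_NM,
                box=_box_from_dimensions(dims),
                time=t,
            )
        )
    return Trajectory(topology, frames, resolution_tag)


def write_table(df: pd.DataFrame, path: str | os.PathLike, params: dict | None = None) -> None:
    """Write a TSV result table with a one-line ``#`` header recording parameters."""
    with open(path, "w") as fh:
        if params:
            items = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
            fh.write(f"# {items}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
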