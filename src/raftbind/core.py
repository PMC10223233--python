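"""Core data model: atoms, topologies, frames, trajectories, replicates.

Internal length unit is nm everywhere (PDB angstroms are converted at the
I/O boundary), times are carried in ns, and boxes are orthorhombic edge
lengths.  These containers are deliberately thin: heavy numerics live in
NumPy arrays cached on the topology.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .config import (
    DEFAULT_LIPID_REFERENCE_ATOMS,
    LIPID_TYPES,
    MoleculeType,
)
from .errors import OrderingError, TopologyError, WindowError


@dataclass(frozen=True)
class Atom:
    """One particle (atom or coarse-grained bead)."""

    atom_id: int
    atom_name: str
    residue_index: int          # 1-based within its molecule/chain
    residue_name: str
    molecule_id: int
    molecule_type: MoleculeType
    chain_id: str | None = None  # protein atoms only


class Topology:
    """Ordered atom list plus lipid/protein annotations.

    Parameters
    ----------
    atoms
        Ordered atoms; ``atom_id`` must be unique.
    lipid_reference_atoms
        Mapping ``molecule_type -> (headgroup reference atom name,
        tuple of ordered acyl-chain atom-name tuples)``.
    protein_sequences
        Mapping ``chain_id -> one-letter residue string``.
    """

    def __init__(
        self,
        atoms: Sequence[Atom],
        lipid_reference_atoms: dict | None = None,
        protein_sequences: dict[str, str] | None = None,
    ):
        self.atoms = list(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise TopologyError("atom_ids are not unique")
        for a in self.atoms:
            if a.molecule_type is MoleculeType.PROTEIN and a.chain_id is None:
                raise TopologyError(f"protein atom {a.atom_id} lacks a chain_id")
        self.lipid_reference_atoms = dict(
            lipid_reference_atoms if lipid_reference_atoms is not None
            else DEFAULT_LIPID_REFERENCE_ATOMS
        )
        self.protein_sequences = dict(protein_sequences or {})
        self._build_arrays()
        self._validate()

    # -- cached arrays ------------------------------------------------------
    def _build_arrays(self) -> None:
        n = len(self.atoms)
        self.molecule_types = np.array([a.molecule_type.value for a in self.atoms])
        self.molecule_ids = np.array([a.molecule_id for a in self.atoms], dtype=np.intp)
        self.residue_indices = np.array([a.residue_index for a in self.atoms], dtype=np.intp)
        self.atom_names = np.array([a.atom_name for a in self.atoms])
        self.chain_ids = np.array(
            [a.chain_id if a.chain_id is not None else "" for a in self.atoms]
        )
        self.indices = np.arange(n, dtype=np.intp)

    def _validate(self) -> None:
        for chain_id, seq in self.protein_sequences.items():
            mask = (self.molecule_types == MoleculeType.PROTEIN.value) & (
                self.chain_ids == chain_id
            )
            if mask.any():
                n_res = len(np.unique(self.residue_indices[mask]))
                if n_res != len(seq):
                    raise TopologyError(
                        f"chain {chain_id}: {n_res} residues but sequence length {len(seq)}"
                    )

    # -- selections ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def type_indices(self, molecule_type: MoleculeType) -> np.ndarray:
        """Atom indices (0-based positions) of one molecule type."""
        return self.indices[self.molecule_types == molecule_type.value]

    def protein_indices(self, chain_id: str | None = None) -> np.ndarray:
        mask = self.molecule_types == MoleculeType.PROTEIN.value
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        return self.indices[mask]

    def protein_chain_ids(self) -> list[str]:
        mask = self.molecule_types == MoleculeType.PROTEIN.value
        seen: list[str] = []
        for cid in self.chain_ids[mask]:
            if cid not in seen:
                seen.append(cid)
        return seen

    def lipid_molecule_ids(self, molecule_type: MoleculeType | None = None) -> np.ndarray:
        """Sorted unique molecule ids of lipids (optionally of one type)."""
        types = (molecule_type,) if molecule_type is not None else LIPID_TYPES
        mask = np.isin(self.molecule_types, [t.value for t in types])
        return np.unique(self.molecule_ids[mask])

    def molecule_atom_indices(self, molecule_id: int) -> np.ndarray:
        return self.indices[self.molecule_ids == molecule_id]

    def molecule_type_of(self, molecule_id: int) -> MoleculeType:
        idx = self.molecule_atom_indices(molecule_id)
        if idx.size == 0:
            raise TopologyError(f"unknown molecule id {molecule_id}")
        return MoleculeType(self.molecule_types[idx[0]])

    def headgroup_index(self, molecule_id: int) -> int:
        """Atom index of the headgroup reference atom of one lipid."""
        mtype = self.molecule_type_of(molecule_id)
        ref = self.lipid_reference_atoms.get(mtype)
        if ref is None:
            raise TopologyError(f"no reference atoms declared for {mtype.value}")
        head_name = ref[0]
        idx = self.molecule_atom_indices(molecule_id)
        hits = idx[self.atom_names[idx] == head_name]
        if hits.size == 0:
            raise TopologyError(
                f"lipid {molecule_id} ({mtype.value}) has no headgroup atom {head_name!r}"
            )
        return int(hits[0])

    def headgroup_indices(self, molecule_type: MoleculeType | None = None) -> dict[int, int]:
        """molecule_id -> headgroup atom index for all lipids (or one type)."""
        out: dict[int, int] = {}
        for mid in self.lipid_molecule_ids(molecule_type):
            out[int(mid)] = self.headgroup_index(int(mid))
        return out

    def chain_carbon_indices(self, molecule_id: int) -> list[np.ndarray]:
        """Per acyl chain, ordered atom indices of the chain carbons/beads."""
        mtype = self.molecule_type_of(molecule_id)
        ref = self.lipid_reference_atoms.get(mtype)
        if ref is None:
            raise TopologyError(f"no reference atoms declared for {mtype.value}")
        idx = self.molecule_atom_indices(molecule_id)
        names = self.atom_names[idx]
        chains = []
        for chain_names in ref[1]:
            chain_idx = []
            for nm in chain_names:
                hits = idx[names == nm]
                if hits.size == 0:
                    raise TopologyError(
                        f"lipid {molecule_id} ({mtype.value}) missing chain atom {nm!r}"
                    )
                chain_idx.append(int(hits[0]))
            chains.append(np.array(chain_idx, dtype=np.intp))
        return chains

    def residue_atom_indices(self, chain_id: str) -> list[np.ndarray]:
        """Per residue (1..L) atom indices of one protein chain."""
        idx = self.protein_indices(chain_id)
        if idx.size == 0:
            raise TopologyError(f"no protein chain {chain_id!r}")
        res = self.residue_indices[idx]
        return [idx[res == r] for r in range(1, int(res.max()) + 1)]


@dataclass
class Frame:
    """Positions (nm) + orthorhombic box (nm) + time stamp (ns)."""

    positions: np.ndarray        # (N, 3) float64, nm
    box: np.ndarray              # (3,) edge lengths, nm
    time: float = 0.0            # ns

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TopologyError("positions must be (N, 3)")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise TopologyError("box must be three positive edge lengths")
        if self.time < 0:
            raise OrderingError("frame time must be non-negative")


@dataclass
class Trajectory:
    """Ordered frames sharing one topology."""

    topology: Topology
    frames: list[Frame]
    resolution_tag: str = "CG"   # "CG" or "AA"

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.positions.shape[0] != n:
                raise TopologyError(
                    f"frame {i}: {f.positions.shape[0]} positions for {n} topology atoms"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise OrderingError("frame times are not strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def effective_times(self, factor: float = 4.0) -> np.ndarray:
        """Times scaled by the coarse-grained speed-up factor (reporting only)."""
        return self.times * factor


@dataclass
class ReplicateSet:
    """Structurally congruent per-replicate results of one analysis kind."""

    label: str
    members: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MeanSem:
    """Replicate mean with its standard error."""

    mean: float
    sem: float
    n: int

    @property
    def single_replicate(self) -> bool:
        return self.n == 1


_TIME_UNITS = {"ns": 1.0, "us": 1e3, "μs": 1e3, "ms": 1e6, "ps": 1e-3}


def parse_window(window: str | tuple[float, float]) -> tuple[float | None, float | None, bool]:
    """Parse a window spec into ``(lo, hi, is_last)``.

    Accepts ``(lo, hi)`` in ns, or a string ``"last <T> <unit>"`` /
    ``"last <T>"`` (ns assumed).  For "last" windows ``lo`` holds the span T.
    """
    if isinstance(window, str):
        parts = window.replace("µ", "μ").split()
        if not parts or parts[0].lower() != "last" or len(parts) not in (2, 3):
            raise WindowError(f"cannot parse window {window!r}")
        try:
            span = float(parts[1])
        except ValueError as exc:
            raise WindowError(f"cannot parse window {window!r}") from exc
        unit = parts[2] if len(parts) == 3 else "ns"
        if unit not in _TIME_UNITS:
            raise WindowError(f"unknown time unit {unit!r}")
        return span * _TIME_UNITS[unit], None, True
    lo, hi = float(window[0]), float(window[1])
    return lo, hi, False


def window_select(traj: Trajectory, window: str | tuple[float, float]) -> Trajectory:
    """Select frames inside a time window, endpoints inclusive.

    ``window`` is either an explicit ``(t_lo, t_hi)`` interval in ns or a
    string like ``"last 5 us"`` / ``"last 50 ns"`` meaning the trailing span
    of the trajectory.
    """
    times = traj.times
    if times.size == 0:
        raise WindowError("empty trajectory")
    lo, hi, is_last = parse_window(window)
    if is_last:
        t_end = times[-1]
        mask = times >= t_end - lo
    else:
        mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise WindowError(f"window {window!r} selects no frames")
    frames = [f for f, keep in zip(traj.frames, mask) if keep]
    return Trajectory(traj.topology, frames, traj.resolution_tag)


def replicate_mean_sem(values: Iterable[float]) -> MeanSem:
    """Arithmetic mean and standard error over independent replicates.

    The SEM uses the sample (n-1) standard deviation divided by sqrt(n);
    a single replicate yields sem = 0, flagged via ``single_replicate``.
    """
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size == 0:
        raise ValueError("replicate_mean_sem requires at least one value")
    mean = float(vals.mean())
    if vals.size == 1:
        return MeanSem(mean, 0.0, 1)
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    return MeanSem(mean, sem, int(vals.size))


def warn(message: str) -> None:
    """Single funnel for analysis warnings (keeps tests quiet-able)."""
    warnings.warn(message, stacklevel=3)
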