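"""Annular lipid shell assignment, composition statistics and energies.

A lipid belongs to the shell bin (inner, outer] whose bounds bracket its
minimum any-atom distance to the membrane-bound protein; lipids beyond the
outermost bound are non-annular.  The standard scheme is 0-0.5, 0.5-1,
1-2 and 2-3 nm, plus the separate 0-1.2 nm shell used to normalize
nonbonded protein-lipid interaction energies (energies are consumed from
tables produced by the MD engine, never recomputed from coordinates).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ENERGY_SHELL, LIPID_TYPES, STANDARD_SHELL_BINS, MoleculeType
from .core import Frame, Topology, Trajectory, replicate_mean_sem, warn, window_select
from .errors import AlignmentError, SchemeError
from .geometry import AtomSelection, pairwise_distances

NON_ANNULAR = -1


@dataclass(frozen=True)
class ShellScheme:
    """Ordered, non-overlapping radial bins (inner, outer] in nm."""

    bins: tuple[tuple[float, float], ...] = STANDARD_SHELL_BINS

    def __post_init__(self) -> None:
        prev = None
        for inner, outer in self.bins:
            if outer <= inner:
                raise SchemeError(f"bin ({inner}, {outer}) has outer <= inner")
            if prev is not None and inner < prev:
                raise SchemeError("shell bins overlap or are out of order")
            prev = outer

    @property
    def outermost(self) -> float:
        return self.bins[-1][1]

    def bin_of(self, d: float) -> int:
        """Bin index for a distance, or NON_ANNULAR (half-open: inner < d <= outer)."""
        for k, (inner, outer) in enumerate(self.bins):
            if inner < d <= outer or (k == 0 and d <= inner):
                return k
        return NON_ANNULAR

    def labels(self) -> list[str]:
        return [f"{inner:g}-{outer:g}" for inner, outer in self.bins]


ENERGY_SHELL_SCHEME = ShellScheme(bins=(ENERGY_SHELL,))


@dataclass
class ShellAssignment:
    """Per-lipid shell bin (or NON_ANNULAR) for one frame."""

    time: float
    scheme: ShellScheme
    bins: dict[int, int]          # molecule_id -> bin index or NON_ANNULAR
    distances: dict[int, float]   # molecule_id -> min distance to protein

    def lipids_in(self, bin_index: int) -> list[int]:
        return sorted(m for m, b in self.bins.items() if b == bin_index)

    @property
    def nonannular(self) -> list[int]:
        return self.lipids_in(NON_ANNULAR)


def assign_shells(
    frame: Frame,
    topology: Topology,
    protein: AtomSelection,
    scheme: ShellScheme = ShellScheme(),
) -> ShellAssignment:
    """Bin every lipid by its minimum atom-atom distance to the protein.

    Whole-lipid (any-atom) membership; water and ions are never part of a
    shell.
    """
    protein.require_nonempty()
    lipid_mask = np.isin(topology.molecule_types, [t.value for t in LIPID_TYPES])
    lipid_idx = topology.indices[lipid_mask]
    lipid_mids = topology.molecule_ids[lipid_mask]
    bins: dict[int, int] = {}
    dists: dict[int, float] = {}
    if lipid_idx.size:
        dmat = pairwise_distances(
            frame.positions[lipid_idx], frame.positions[protein.indices], frame.box
        )
        per_atom = dmat.min(axis=1)
        for mid in np.unique(lipid_mids):
            d = float(per_atom[lipid_mids == mid].min())
            dists[int(mid)] = d
            bins[int(mid)] = scheme.bin_of(d)
    return ShellAssignment(frame.time, scheme, bins, dists)


def shells_over_trajectory(
    traj: Trajectory,
    protein: AtomSelection,
    scheme: ShellScheme = ShellScheme(),
    window: str | tuple[float, float] | None = None,
) -> list[ShellAssignment]:
    if window is not None:
        traj = window_select(traj, window)
    return [assign_shells(f, traj.topology, protein, scheme) for f in traj.frames]


def _frame_composition(
    assignment: ShellAssignment, topology: Topology, bin_index: int
) -> dict | None:
    members = assignment.lipids_in(bin_index)
    if not members:
        return None
    counts = {t.value: 0 for t in LIPID_TYPES}
    for mid in members:
        counts[topology.molecule_type_of(mid).value] += 1
    total = len(members)
    row = {"n_lipids": total}
    for t, c in counts.items():
        row[f"{t}_count"] = c
        row[f"{t}_pct"] = 100.0 * c / total
    return row


def shell_composition(
    assignments: list[ShellAssignment],
    topology: Topology,
    include_nonannular: bool = True,
) -> pd.DataFrame:
    """Window-mean shell composition (per bin: counts and percentages).

    Frames in which a bin is empty contribute no percentage sample for that
    bin (excluded with a warning).  Returns one row per shell bin with the
    window means; replicate aggregation happens in
    :func:`replicate_composition`.
    """
    scheme = assignments[0].scheme
    bin_ids = list(range(len(scheme.bins)))
    if include_nonannular:
        bin_ids.append(NON_ANNULAR)
    rows = []
    for b in bin_ids:
        samples = []
        n_empty = 0
        for a in assignments:
            row = _frame_composition(a, topology, b)
            if row is None:
                n_empty += 1
            else:
                samples.append(row)
        label = "nAL" if b == NON_ANNULAR else scheme.labels()[b]
        if n_empty:
            warn(f"shell {label}: {n_empty} frame(s) empty, excluded from averages")
        if not samples:
            continue
        df = pd.DataFrame(samples)
        out = {"shell": label}
        out.update(df.mean().to_dict())
        rows.append(out)
    return pd.DataFrame(rows)


def replicate_composition(per_replicate: list[pd.DataFrame]) -> pd.DataFrame:
    """Replicate mean +- SEM of window-mean shell compositions."""
    rows = []
    shells = per_replicate[0]["shell"].tolist()
    value_cols = [c for c in per_replicate[0].columns if c != "shell"]
    for shell in shells:
        row: dict = {"shell": shell}
        for col in value_cols:
            vals = []
            for df in per_replicate:
                hit = df.loc[df["shell"] == shell, col]
                if len(hit):
                    vals.append(float(hit.iloc[0]))
            if not vals:
                continue
            ms = replicate_mean_sem(vals)
            row[col] = ms.mean
            row[f"{col}_sem"] = ms.sem
        rows.append(row)
    return pd.DataFrame(rows)


def nonannular_control(assignment: ShellAssignment) -> list[int]:
    """Lipids outside every shell bin (the non-annular complement)."""
    return assignment.nonannular


@dataclass
class EnergyRecord:
    """Normalized protein-lipid interaction energy time series."""

    partner: str
    times: np.ndarray
    e_lj: np.ndarray
    e_coulomb: np.ndarray
    n_shell: np.ndarray
    normalized_lj: np.ndarray = field(init=False)
    normalized_coulomb: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.normalized_lj = self.e_lj / self.n_shell
        self.normalized_coulomb = self.e_coulomb / self.n_shell

    @property
    def normalized_total(self) -> np.ndarray:
        return self.normalized_lj + self.normalized_coulomb


def normalized_interaction_energy(
    energy_table: pd.DataFrame,
    shell_assignments: list[ShellAssignment],
    topology: Topology,
    partner: MoleculeType | str,
) -> EnergyRecord:
    """Divide per-time nonbonded energies by the 1.2 nm shell lipid count.

    ``energy_table`` columns: time (ns), partner_type, E_LJ, E_Coulomb
    (kJ/mol).  The shell assignments must be computed with the energy-shell
    scheme; their times must match the table's rows exactly.  Time points
    with an empty shell are excluded with a warning.
    """
    pname = MoleculeType(partner).value
    sub = energy_table[energy_table["partner_type"] == pname]
    times_tab = sub["time"].to_numpy(dtype=np.float64)
    times_shell = np.array([a.time for a in shell_assignments])
    if times_tab.size != times_shell.size or not np.allclose(times_tab, times_shell):
        raise AlignmentError("energy table and shell-count time axes differ")
    n_shell = np.array(
        [
            sum(
                1
                for mid in a.lipids_in(0)
                if topology.molecule_type_of(mid).value == pname
            )
            for a in shell_assignments
        ],
        dtype=np.float64,
    )
    keep = n_shell >= 1
    if not keep.all():
        warn(f"{int((~keep).sum())} time point(s) with empty 1.2 nm shell excluded")
    return EnergyRecord(
        partner=pname,
        times=times_tab[keep],
        e_lj=sub["E_LJ"].to_numpy(dtype=np.float64)[keep],
        e_coulomb=sub["E_Coulomb"].to_numpy(dtype=np.float64)[keep],
        n_shell=n_shell[keep],
    )
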