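"""Binding kinetics and residue-resolved binding spectra.

Mindist/contact time series against each partner species, detection of the
membrane-binding time (the "abrupt transition" from a large fluctuating
protein-lipid minimum distance to a small stable one, formalized as a
threshold + dwell + occupancy criterion), per-residue minimum-distance
spectra averaged over time, chains and replicates, and the sequence-level
descriptors (Kyte-Doolittle hydropathy profile, net charge) used to
interpret the spectra.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import (
    BINDING_D_BOUND,
    BINDING_OCCUPANCY,
    CONTACT_CUTOFF,
    HYDROPATHY_WINDOW,
    MoleculeType,
    SPECTRUM_SMOOTHING_WINDOW,
)
from .core import Trajectory, replicate_mean_sem, window_select
from .errors import RaftbindError, SelectionError
from .geometry import AtomSelection, count_contacts, group_min_distance

#: Kyte-Doolittle hydropathy scale (kcal/mol-free units, standard table).
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass
class MindistSeries:
    """Protein-partner minimum distance and contact count vs time."""

    partner: str
    times: np.ndarray
    d_min: np.ndarray
    contacts: np.ndarray
    contact_cutoff: float = CONTACT_CUTOFF
    argmin_atoms: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.d_min = np.asarray(self.d_min, dtype=np.float64)
        self.contacts = np.asarray(self.contacts, dtype=np.intp)
        if not (len(self.times) == len(self.d_min) == len(self.contacts)):
            raise RaftbindError("mindist series arrays must have equal length")


@dataclass
class BindingEvent:
    """Detected binding time (ns) or None, with the criterion that fired."""

    t_bind: float | None
    d_bound: float
    dwell: float
    occupancy: float
    bound_leaflet: str | None = None
    bound_molecule_id: int | None = None


@dataclass
class ResidueSpectrum:
    """Per-residue per-partner window-averaged minimum distances.

    ``per_chain[partner]`` is a (n_chains, L) array of window means; the
    chain-averaged spectrum is its mean over chains.  Replicate aggregation
    happens in :func:`aggregate_spectra`.
    """

    partners: list[str]
    chain_ids: list[str]
    per_chain: dict[str, np.ndarray]
    window: str | tuple

    @property
    def n_residues(self) -> int:
        return next(iter(self.per_chain.values())).shape[1]

    def chain_averaged(self, partner: str) -> np.ndarray:
        return self.per_chain[partner].mean(axis=0)


@dataclass
class HydropathyProfile:
    sequence: str
    raw: np.ndarray
    smoothed: np.ndarray
    window: int
    peaks: list[int]     # 1-based residue numbers, local maxima of smoothed
    dips: list[int]


@dataclass
class SequenceRecord:
    sequence: str
    net_charge: int
    basic_positions: list[int]   # 1-based


def partner_selection(topology, partner: MoleculeType | str) -> AtomSelection:
    """All atoms of a partner species (a lipid type or WATER)."""
    mtype = MoleculeType(partner)
    idx = topology.type_indices(mtype)
    sel = AtomSelection(mtype.value, idx)
    sel.require_nonempty()
    return sel


def mindist_timeseries(
    traj: Trajectory,
    protein: AtomSelection,
    partner: MoleculeType | str,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> MindistSeries:
    """Per-frame group minimum distance and contact count vs one partner."""
    protein.require_nonempty()
    part = partner_selection(traj.topology, partner)
    times, dmins, ncont, argmins = [], [], [], []
    for frame in traj.frames:
        d, pair = group_min_distance(protein, part, frame)
        times.append(frame.time)
        dmins.append(d)
        argmins.append(pair)
        ncont.append(count_contacts(protein, part, frame, contact_cutoff))
    return MindistSeries(
        partner=MoleculeType(partner).value,
        times=np.array(times),
        d_min=np.array(dmins),
        contacts=np.array(ncont),
        contact_cutoff=contact_cutoff,
        argmin_atoms=argmins,
    )


def detect_binding_time(
    series: MindistSeries,
    d_bound: float = BINDING_D_BOUND,
    dwell: float = 500.0,
    occupancy: float = BINDING_OCCUPANCY,
) -> BindingEvent:
    """Earliest time of the abrupt transition to a stable bound state.

    ``t_bind`` is the earliest sample time t such that (i) within
    [t, t + dwell] the fraction of samples with d_min <= d_bound is at
    least ``occupancy`` and (ii) after t the series never exceeds
    ``d_bound`` for a contiguous run longer than (1 - occupancy) * dwell.
    Returns ``t_bind=None`` if no such t exists.
    """
    t = series.times
    d = series.d_min
    if t.size == 0:
        raise RaftbindError("empty mindist series")
    span = t[-1] - t[0]
    if dwell > span:
        raise RaftbindError(f"dwell {dwell} ns exceeds series span {span} ns")
    below = d <= d_bound
    max_excursion = (1.0 - occupancy) * dwell

    for i in np.where(below)[0]:
        in_win = (t >= t[i]) & (t <= t[i] + dwell)
        if below[in_win].mean() < occupancy:
            continue
        # excursion check over the whole remainder of the series
        ok = True
        run_start = None
        for j in range(i, t.size):
            if not below[j]:
                if run_start is None:
                    run_start = t[j]
                run_len = t[j] - run_start + _dt_at(t, j)
                if run_len > max_excursion:
                    ok = False
                    break
            else:
                run_start = None
        if ok:
            return BindingEvent(float(t[i]), d_bound, dwell, occupancy)
    return BindingEvent(None, d_bound, dwell, occupancy)


def _dt_at(t: np.ndarray, j: int) -> float:
    if j + 1 < t.size:
        return float(t[j + 1] - t[j])
    if j > 0:
        return float(t[j] - t[j - 1])
    return 0.0


def bound_leaflet(
    traj: Trajectory, series: MindistSeries, event: BindingEvent, leaflets
) -> BindingEvent:
    """Annotate a binding event with the leaflet of the lipid achieving d_min."""
    if event.t_bind is None:
        return event
    i = int(np.argmin(np.abs(series.times - event.t_bind)))
    _, lipid_atom = series.argmin_atoms[i]
    mid = int(traj.topology.molecule_ids[lipid_atom])
    event.bound_molecule_id = mid
    event.bound_leaflet = leaflets.labels.get(mid)
    return event


def residue_mindist_spectrum(
    traj: Trajectory,
    window: str | tuple[float, float] | None,
    partners: list[MoleculeType | str],
) -> ResidueSpectrum:
    """Window-mean minimum distance from each residue to each partner species.

    For every residue index r (pooled over chains) and partner, the minimum
    distance between residue-r atoms and partner atoms is averaged over the
    window frames; per-chain means are kept so replicate aggregation can
    average chains first.
    """
    if window is not None:
        traj = window_select(traj, window)
    topo = traj.topology
    chain_ids = topo.protein_chain_ids()
    if not chain_ids:
        raise SelectionError("no protein chains in topology")
    residue_atoms = {cid: topo.residue_atom_indices(cid) for cid in chain_ids}
    for cid, groups in residue_atoms.items():
        for r, g in enumerate(groups, start=1):
            if g.size == 0:
                raise SelectionError(f"chain {cid} residue {r} has no atoms")
    n_res = len(residue_atoms[chain_ids[0]])
    part_sel = {MoleculeType(p).value: partner_selection(topo, p) for p in partners}

    # one distance matrix per (frame, partner); residue minima read off it
    all_protein = np.concatenate([np.concatenate(residue_atoms[cid]) for cid in chain_ids])
    slices: list[tuple[int, int, slice]] = []
    off = 0
    for ci, cid in enumerate(chain_ids):
        for r, atoms in enumerate(residue_atoms[cid]):
            slices.append((ci, r, slice(off, off + atoms.size)))
            off += atoms.size

    sums = {p: np.zeros((len(chain_ids), n_res)) for p in part_sel}
    from .geometry import pairwise_distances

    for frame in traj.frames:
        for p, sel in part_sel.items():
            per_atom = pairwise_distances(
                frame.positions[all_protein], frame.positions[sel.indices], frame.box
            ).min(axis=1)
            for ci, r, sl in slices:
                sums[p][ci, r] += per_atom[sl].min()
    nf = traj.n_frames
    per_chain = {p: s / nf for p, s in sums.items()}
    return ResidueSpectrum(
        partners=list(part_sel), chain_ids=chain_ids, per_chain=per_chain,
        window=window if window is not None else "all",
    )


def aggregate_spectra(
    spectra: list[ResidueSpectrum], partner: str
) -> tuple[np.ndarray, np.ndarray]:
    """Replicate mean +- SEM of chain-averaged spectra.

    Chains are averaged within each replicate first, then the SEM is taken
    across replicates, so the error bar reflects replicate scatter.
    """
    per_rep = np.stack([s.chain_averaged(partner) for s in spectra])
    stats = [replicate_mean_sem(per_rep[:, r]) for r in range(per_rep.shape[1])]
    return (
        np.array([m.mean for m in stats]),
        np.array([m.sem for m in stats]),
    )


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; edges use the truncated window."""
    values = np.asarray(values, dtype=np.float64)
    if window < 1 or window % 2 == 0:
        raise RaftbindError("moving-average window must be a positive odd integer")
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo, hi = max(0, i - half), min(values.size, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def smooth_spectrum(values: np.ndarray, window: int = SPECTRUM_SMOOTHING_WINDOW) -> np.ndarray:
    """3-point moving average applied to spectra before peak/dip reporting."""
    return moving_average(values, window)


def _local_extrema(values: np.ndarray, kind: str) -> list[int]:
    sign = 1.0 if kind == "max" else -1.0
    v = sign * values
    out = []
    for i in range(1, v.size - 1):
        if v[i] > v[i - 1] and v[i] >= v[i + 1]:
            out.append(i + 1)  # 1-based
    return out


def hydropathy_profile(sequence: str, window: int = HYDROPATHY_WINDOW) -> HydropathyProfile:
    """Kyte-Doolittle hydropathy profile with a centered moving-average fit.

    Peaks/dips are local extrema of the smoothed profile; the raw scale
    values remain available per residue (the per-residue hydrophobicity of
    a peak is read off the raw profile).
    """
    sequence = sequence.strip().upper()
    try:
        raw = np.array([KYTE_DOOLITTLE[c] for c in sequence])
    except KeyError as exc:
        raise RaftbindError(f"unknown residue letter {exc.args[0]!r}") from exc
    smoothed = moving_average(raw, window)
    return HydropathyProfile(
        sequence=sequence,
        raw=raw,
        smoothed=smoothed,
        window=window,
        peaks=_local_extrema(smoothed, "max"),
        dips=_local_extrema(smoothed, "min"),
    )


def sequence_charge(sequence: str) -> SequenceRecord:
    """Net charge as the count of basic residues (K + R); termini and
    histidine treated as neutral."""
    sequence = sequence.strip().upper()
    for c in sequence:
        if c not in KYTE_DOOLITTLE:
            raise RaftbindError(f"unknown residue letter {c!r}")
    basic = [i + 1 for i, c in enumerate(sequence) if c in ("K", "R")]
    return SequenceRecord(sequence, len(basic), basic)
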