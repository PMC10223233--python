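"""Lipid nanodomain classification and cluster detection.

A DPPC that has any atom within the proximity threshold (default 0.5 nm) of
any same-leaflet DLPC atom belongs to the mixed (Lod) domain, otherwise to
the ordered (Lo) domain; symmetrically DLPC is Lod or Ld.  Cholesterol is
assigned the domain of its nearest same-leaflet PC atom within the
threshold, or left unassigned.  Anionic/ganglioside lipids (POPS, GM1) form
single-linkage clusters under a linkage cutoff.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .config import (
    CLUSTER_LINKAGE_CUTOFF,
    DOMAIN_PROXIMITY_THRESHOLD,
    MoleculeType,
)
from .core import Frame, Topology, Trajectory, warn, window_select
from .errors import SelectionError
from .geometry import AtomSelection, NeighborQuery, neighbor_pairs, pairwise_distances

TOP = "TOP"
BOTTOM = "BOTTOM"
LO, LD, LOD, UNASSIGNED = "Lo", "Ld", "Lod", "UNASSIGNED"


@dataclass
class LeafletLabel:
    """Per-lipid leaflet assignment (molecule_id -> TOP/BOTTOM)."""

    labels: dict[int, str]
    midplane_z: float

    def ids_in(self, leaflet: str) -> list[int]:
        return [mid for mid, lab in self.labels.items() if lab == leaflet]


@dataclass
class DomainLabeling:
    """Per-lipid Lo/Ld/Lod (PC) and Lo/Ld/Lod/UNASSIGNED (CHOL) labels."""

    pc_labels: dict[int, str] = field(default_factory=dict)
    chol_labels: dict[int, str] = field(default_factory=dict)
    time: float = 0.0
    threshold: float = DOMAIN_PROXIMITY_THRESHOLD


@dataclass
class ClusterSet:
    """Single-linkage clusters of one lipid type."""

    lipid_type: MoleculeType
    clusters: list[frozenset[int]]
    linkage_cutoff: float

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def __len__(self) -> int:
        return len(self.clusters)


def assign_leaflets(
    frame: Frame,
    topology: Topology,
    monolayer_spread: float = 1.5,
) -> LeafletLabel:
    """Split lipids into TOP/BOTTOM leaflets by headgroup z against the midplane.

    The midplane is the mean z of all headgroup reference atoms; a lipid is
    TOP when its reference sits above it.  If the spread of reference z
    values is below ``monolayer_spread`` (nm) the input is treated as a
    single leaflet: everything is labelled TOP with a warning.
    """
    heads = topology.headgroup_indices()
    if not heads:
        raise SelectionError("no lipids with headgroup reference atoms")
    mids = np.array(list(heads.keys()), dtype=np.intp)
    z = frame.positions[np.array(list(heads.values()), dtype=np.intp), 2]
    if z.max() - z.min() < monolayer_spread:
        warn("headgroup spread below bilayer threshold; treating input as one leaflet")
        return LeafletLabel({int(m): TOP for m in mids}, float(z.mean()))
    midplane = float(z.mean())
    labels = {int(m): (TOP if zz > midplane else BOTTOM) for m, zz in zip(mids, z)}
    return LeafletLabel(labels, midplane)


def _type_atoms_in_leaflet(
    topology: Topology, leaflets: LeafletLabel, mtype: MoleculeType, leaflet: str
) -> tuple[np.ndarray, np.ndarray]:
    """(atom indices, parallel molecule ids) of one lipid type in one leaflet."""
    idx = topology.type_indices(mtype)
    if idx.size == 0:
        return idx, idx
    mids = topology.molecule_ids[idx]
    keep = np.array([leaflets.labels.get(int(m)) == leaflet for m in mids])
    return idx[keep], mids[keep]


def classify_pc_domains(
    frame: Frame,
    topology: Topology,
    leaflets: LeafletLabel | None = None,
    threshold: float = DOMAIN_PROXIMITY_THRESHOLD,
) -> DomainLabeling:
    """Label every DPPC as Lo/Lod and every DLPC as Ld/Lod.

    A lipid is Lod iff any of its atoms lies within ``threshold`` of any
    atom of the other PC type in the same leaflet.  With one PC type absent
    the present type defaults to its pure domain.
    """
    if leaflets is None:
        leaflets = assign_leaflets(frame, topology)
    labeling = DomainLabeling(time=frame.time, threshold=threshold)
    for mid in topology.lipid_molecule_ids(MoleculeType.DPPC):
        labeling.pc_labels[int(mid)] = LO
    for mid in topology.lipid_molecule_ids(MoleculeType.DLPC):
        labeling.pc_labels[int(mid)] = LD

    for leaflet in (TOP, BOTTOM):
        dppc_idx, dppc_mid = _type_atoms_in_leaflet(
            topology, leaflets, MoleculeType.DPPC, leaflet
        )
        dlpc_idx, dlpc_mid = _type_atoms_in_leaflet(
            topology, leaflets, MoleculeType.DLPC, leaflet
        )
        if dppc_idx.size == 0 or dlpc_idx.size == 0:
            continue
        a = AtomSelection(f"DPPC/{leaflet}", dppc_idx)
        b = AtomSelection(f"DLPC/{leaflet}", dlpc_idx)
        pairs, _ = neighbor_pairs(frame, a, b, NeighborQuery(threshold))
        if len(pairs) == 0:
            continue
        pos_of = {int(g): k for k, g in enumerate(dppc_idx)}
        pos_of_b = {int(g): k for k, g in enumerate(dlpc_idx)}
        for i, j in pairs:
            labeling.pc_labels[int(dppc_mid[pos_of[int(i)]])] = LOD
            labeling.pc_labels[int(dlpc_mid[pos_of_b[int(j)]])] = LOD
    return labeling


def assign_chol_domains(
    frame: Frame,
    topology: Topology,
    pc_labels: DomainLabeling,
    leaflets: LeafletLabel | None = None,
    threshold: float = DOMAIN_PROXIMITY_THRESHOLD,
) -> DomainLabeling:
    """Label cholesterol by the domain of its nearest same-leaflet PC atom.

    A CHOL with no PC atom within ``threshold`` stays UNASSIGNED.  The
    nearest-atom rule turns the possibly multi-valued "within 0.5 nm of a
    domain" relation into a partition.
    """
    if leaflets is None:
        leaflets = assign_leaflets(frame, topology)
    for mid in topology.lipid_molecule_ids(MoleculeType.CHOL):
        pc_labels.chol_labels[int(mid)] = UNASSIGNED

    for leaflet in (TOP, BOTTOM):
        chol_idx, chol_mid = _type_atoms_in_leaflet(
            topology, leaflets, MoleculeType.CHOL, leaflet
        )
        if chol_idx.size == 0:
            continue
        pc_idx_list, pc_mid_list = [], []
        for t in (MoleculeType.DPPC, MoleculeType.DLPC):
            ti, tm = _type_atoms_in_leaflet(topology, leaflets, t, leaflet)
            pc_idx_list.append(ti)
            pc_mid_list.append(tm)
        pc_idx = np.concatenate(pc_idx_list)
        pc_mid = np.concatenate(pc_mid_list)
        if pc_idx.size == 0:
            continue
        dmat = pairwise_distances(
            frame.positions[chol_idx], frame.positions[pc_idx], frame.box
        )
        for mid in np.unique(chol_mid):
            rows = np.where(chol_mid == mid)[0]
            sub = dmat[rows]
            j = int(np.argmin(sub.min(axis=0)))
            if sub[:, j].min() <= threshold:
                pc_labels.chol_labels[int(mid)] = pc_labels.pc_labels[int(pc_mid[j])]
    return pc_labels


def find_clusters(
    frame: Frame,
    topology: Topology,
    lipid_type: MoleculeType,
    linkage_cutoff: float = CLUSTER_LINKAGE_CUTOFF,
) -> ClusterSet:
    """Single-linkage clusters: lipids linked iff any inter-lipid atom pair
    is within the cutoff; clusters are the connected components, reported
    largest first."""
    idx = topology.type_indices(lipid_type)
    if idx.size == 0:
        warn(f"no {lipid_type.value} lipids present; empty cluster set")
        return ClusterSet(lipid_type, [], linkage_cutoff)
    mids = topology.molecule_ids[idx]
    g = nx.Graph()
    g.add_nodes_from(int(m) for m in np.unique(mids))
    sel = AtomSelection(lipid_type.value, idx)
    pairs, _ = neighbor_pairs(frame, sel, sel, NeighborQuery(linkage_cutoff))
    pos_of = {int(gidx): int(m) for gidx, m in zip(idx, mids)}
    for i, j in pairs:
        mi, mj = pos_of[int(i)], pos_of[int(j)]
        if mi != mj:
            g.add_edge(mi, mj)
    comps = [frozenset(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(lipid_type, comps, linkage_cutoff)


def cluster_domain_context(
    frame: Frame,
    topology: Topology,
    clusters: ClusterSet,
    pc_labels: DomainLabeling,
    threshold: float = DOMAIN_PROXIMITY_THRESHOLD,
) -> list[str | None]:
    """Majority PC domain within ``threshold`` of each cluster's members.

    Gives the domain context of a PS-/GM1-cluster (e.g. a GM1 cluster
    sitting inside the ordered domain); ``None`` when no PC lipid is close.
    """
    pc_idx = np.concatenate(
        [topology.type_indices(MoleculeType.DPPC), topology.type_indices(MoleculeType.DLPC)]
    )
    out: list[str | None] = []
    for cluster in clusters.clusters:
        member_idx = np.concatenate(
            [topology.molecule_atom_indices(m) for m in sorted(cluster)]
        )
        if pc_idx.size == 0:
            out.append(None)
            continue
        dmat = pairwise_distances(
            frame.positions[pc_idx], frame.positions[member_idx], frame.box
        )
        near = dmat.min(axis=1) <= threshold
        near_mids = np.unique(topology.molecule_ids[pc_idx][near])
        if near_mids.size == 0:
            out.append(None)
            continue
        votes: dict[str, int] = {}
        for m in near_mids:
            lab = pc_labels.pc_labels.get(int(m))
            if lab:
                votes[lab] = votes.get(lab, 0) + 1
        out.append(max(sorted(votes), key=lambda k: votes[k]) if votes else None)
    return out


def domain_composition_timeseries(
    traj: Trajectory,
    window: str | tuple[float, float] | None = None,
    threshold: float = DOMAIN_PROXIMITY_THRESHOLD,
    linkage_cutoff: float = CLUSTER_LINKAGE_CUTOFF,
):
    """Per-frame domain counts and window means.

    Returns ``(DataFrame, means)`` where the frame rows hold the counts of
    Lo-DPPC, Lod-DPPC, Ld-DLPC, Lod-DLPC, the three CHOL domain counts plus
    unassigned CHOL, and POPS/GM1 cluster counts.  Counts conserve totals
    by construction.
    """
    import pandas as pd

    if window is not None:
        traj = window_select(traj, window)
    rows = []
    for frame in traj.frames:
        leaflets = assign_leaflets(frame, traj.topology)
        lab = classify_pc_domains(frame, traj.topology, leaflets, threshold)
        lab = assign_chol_domains(frame, traj.topology, lab, leaflets, threshold)
        row = {"time": frame.time}
        pc_types = {
            int(m): traj.topology.molecule_type_of(int(m)) for m in lab.pc_labels
        }
        for key, dom, t in (
            ("Lo_DPPC", LO, MoleculeType.DPPC),
            ("Lod_DPPC", LOD, MoleculeType.DPPC),
            ("Ld_DLPC", LD, MoleculeType.DLPC),
            ("Lod_DLPC", LOD, MoleculeType.DLPC),
        ):
            row[key] = sum(
                1 for m, lab_ in lab.pc_labels.items()
                if lab_ == dom and pc_types[m] is t
            )
        for dom in (LO, LD, LOD, UNASSIGNED):
            row[f"{dom}_CHOL"] = sum(1 for v in lab.chol_labels.values() if v == dom)
        for t in (MoleculeType.POPS, MoleculeType.GM1):
            if traj.topology.type_indices(t).size:
                cs = find_clusters(frame, traj.topology, t, linkage_cutoff)
                row[f"n_clusters_{t.value}"] = len(cs)
            else:
                row[f"n_clusters_{t.value}"] = 0
        rows.append(row)
    df = pd.DataFrame(rows)
    means = df.drop(columns=["time"]).mean().to_dict()
    return df, means
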