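"""Synthetic raft systems with exactly known ground truth.

Builds planar two-leaflet bilayers with a saturated-lipid (DPPC + CHOL)
ordered disk inside an unsaturated (DLPC) background, an optional mixed
boundary ring of close DPPC/DLPC pairs, one-leaflet POPS or GM1 clusters,
placeholder water/ions, and a multi-chain one-bead-per-residue oligomer
that diffuses above the membrane and binds at a prescribed time with
prescribed anchor residues.  Everything is kinematic (scripted positions
plus jitter, no forces): the purpose is to exercise the analysis stages
against labels that are true by construction.

Geometry margins are chosen so the construction's labels are recoverable
exactly: regions of different PC type are separated by empty rings much
wider than the 0.5 nm proximity threshold, mixed-ring pairs sit 0.4 nm
apart (always within it), and cluster members sit 0.45 nm apart (always
within the linkage cutoff) while clusters are kilometres — well, >=3 nm —
apart.
"""
from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import (
    DEFAULT_ANCHOR_RESIDUES,
    DEFAULT_LIPID_REFERENCE_ATOMS,
    HIAPP_SEQUENCE,
    MoleculeType,
)
from .core import Atom, Frame, Topology, Trajectory
from .errors import SpecError
from .folding import CATEGORIES, CODE_TO_CATEGORY, SS_CODES, SSMatrix
from .io import ONE_TO_THREE
from .nanodomains import BOTTOM, TOP

LO, LD, LOD = "Lo", "Ld", "Lod"


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic raft + oligomer system.

    Defaults emulate the published study conditions at reduced lateral
    scale: CO-raft composition scaled by 1/12 (69 DPPC : 45 DLPC :
    48 CHOL), a ~22x22 nm membrane scaled to 12x12 nm, protein start
    height >= 5 nm above the surface, replicate x-offsets of 0/+2/-2 nm and
    anchor residues 16 and 26 of the 37-residue amylin sequence.
    """

    box_xy: float = 12.0
    box_z: float = 14.0
    membrane_center_z: float = 5.0
    thickness: float = 4.0
    lattice_spacing: float = 0.8
    jitter_sigma: float = 0.02
    gap: float = 2.0                     # empty ring width isolating regions
    n_dppc: int = 69
    n_dlpc: int = 45
    n_chol: int = 48
    lod_pairs: int = 0                   # mixed-ring DPPC/DLPC pairs per leaflet
    pair_offset: float = 0.4
    chain_beads: int = 4
    chain_bead_spacing: float = 0.3
    tilt_by_region: dict = field(
        default_factory=lambda: {LO: 10.0, LD: 30.0, LOD: 20.0}
    )
    cluster_type: str | None = None      # "POPS" or "GM1"
    cluster_sizes: tuple = (12,)
    cluster_leaflet: str = TOP
    cluster_spacing: float = 0.45
    cluster_in_disk: bool | None = None  # None: GM1 in the ordered disk, POPS at the edge
    water: bool = True
    water_spacing: float = 1.2
    water_layers: int = 2
    n_ions: int = 4
    protein_chains: int = 1
    sequence: str = HIAPP_SEQUENCE
    start_height: float = 5.0
    binding_time: float = 100.0          # ns
    anchor_residues: tuple = DEFAULT_ANCHOR_RESIDUES
    binding_mode: str = "anchored"       # "anchored" or "nterm"
    n_frames: int = 200
    dt: float = 1.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.jitter_sigma < 0 or self.lattice_spacing <= 0:
            raise SpecError("jitter and lattice spacing must be non-negative/positive")
        if min(self.n_dppc, self.n_dlpc, self.n_chol) < 0:
            raise SpecError("lipid counts must be non-negative")
        if self.replicate not in (1, 2, 3):
            raise SpecError("replicate index must be 1, 2 or 3")
        for r in self.anchor_residues:
            if not 1 <= r <= len(self.sequence):
                raise SpecError(f"anchor residue {r} outside sequence 1..{len(self.sequence)}")
        if self.binding_time >= self.n_frames * self.dt:
            raise SpecError("binding time must fall inside the trajectory span")


@dataclass
class GroundTruth:
    """Sidecar labels consistent with the emitted coordinates by construction."""

    pc_domains: dict[int, str] = field(default_factory=dict)
    chol_domains: dict[int, str] = field(default_factory=dict)
    leaflets: dict[int, str] = field(default_factory=dict)
    clusters: dict[str, list[list[int]]] = field(default_factory=dict)
    cluster_context: dict[str, list[str | None]] = field(default_factory=dict)
    tilt_by_region: dict[str, float] = field(default_factory=dict)
    thickness: float | None = None
    binding_time: float | None = None
    anchor_residues: tuple = ()
    contact_residues: tuple = ()
    binding_leaflet: str | None = None
    s_true: float | None = None
    stationary: dict[str, float] | None = None

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


#: replicate index -> initial protein x-offset (nm)
REPLICATE_X_OFFSETS = {1: 0.0, 2: +2.0, 3: -2.0}


class _Builder:
    """Accumulates atoms + positions with sequential ids."""

    def __init__(self) -> None:
        self.atoms: list[Atom] = []
        self.pos: list[np.ndarray] = []
        self.mol_counter = 0

    def add_molecule(
        self,
        mtype: MoleculeType,
        resname: str,
        names: list[str],
        coords: np.ndarray,
        chain_id: str | None = None,
        residue_indices: list[int] | None = None,
    ) -> int:
        self.mol_counter += 1
        mid = self.mol_counter
        for k, (nm, xyz) in enumerate(zip(names, coords)):
            ridx = residue_indices[k] if residue_indices is not None else 1
            self.atoms.append(
                Atom(
                    atom_id=len(self.atoms) + 1,
                    atom_name=nm,
                    residue_index=ridx,
                    residue_name=resname,
                    molecule_id=mid,
                    molecule_type=mtype,
                    chain_id=chain_id,
                )
            )
            self.pos.append(np.asarray(xyz, dtype=np.float64))
        return mid

    def positions(self) -> np.ndarray:
        return np.vstack(self.pos)


def _chain_names(n: int, suffix: str) -> list[str]:
    return [f"C{k}{suffix}" for k in range(1, n + 1)]


def _pc_coords(
    head: np.ndarray,
    down: float,
    tilt_deg: float,
    azimuths: tuple[float, float],
    n_beads: int,
    spacing: float,
) -> tuple[list[str], np.ndarray]:
    """Head bead + two straight tilted chains; ``down`` is -1 for the top
    leaflet (chains descend) and +1 for the bottom."""
    names = ["PO4"] + _chain_names(n_beads, "A") + _chain_names(n_beads, "B")
    coords = [head]
    theta = math.radians(tilt_deg)
    for offs, phi in zip(((-0.1, 0.0), (0.1, 0.0)), azimuths):
        start = head + np.array([offs[0], offs[1], 0.0])
        d = np.array(
            [
                math.sin(theta) * math.cos(phi),
                math.sin(theta) * math.sin(phi),
                down * math.cos(theta),
            ]
        )
        for j in range(1, n_beads + 1):
            coords.append(start + j * spacing * d)
    return names, np.vstack(coords)


def _lattice_sites(box_xy: float, spacing: float) -> np.ndarray:
    n = int(box_xy // spacing)
    xs = (np.arange(n) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _cluster_offsets(m: int, spacing: float) -> np.ndarray:
    """First m square-grid offsets sorted by radius (connected at spacing)."""
    k = int(math.ceil(math.sqrt(m))) + 2
    rng = np.arange(-k, k + 1)
    gx, gy = np.meshgrid(rng, rng, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float) * spacing
    order = np.lexsort((np.arctan2(pts[:, 1], pts[:, 0]), np.hypot(pts[:, 0], pts[:, 1])))
    return pts[order][:m]


def _build_membrane(spec: SyntheticSpec) -> tuple[_Builder, GroundTruth, dict]:
    """Deterministic (jitter-free) membrane skeleton + ground-truth labels."""
    b = _Builder()
    gt = GroundTruth(
        tilt_by_region=dict(spec.tilt_by_region), thickness=spec.thickness
    )
    cx = cy = spec.box_xy / 2.0
    z_mid = spec.membrane_center_z
    half = spec.thickness / 2.0
    a = spec.lattice_spacing
    nb, sp = spec.chain_beads, spec.chain_bead_spacing
    region_of: dict[int, str] = {}

    # azimuths cycle deterministically so chains fan out but reproducibly
    azi_cycle = [(k * 2.399963) % (2 * math.pi) for k in range(64)]

    for leaflet, sign in ((TOP, -1.0), (BOTTOM, +1.0)):
        z_head = z_mid - sign * half  # TOP above midplane
        sites = _lattice_sites(spec.box_xy, a)
        r = np.hypot(sites[:, 0] - cx, sites[:, 1] - cy)
        order = np.argsort(r, kind="stable")
        sites, r = sites[order], r[order]

        # one-leaflet cluster: carve a hole and lay members around the center
        cluster_positions: list[np.ndarray] = []
        in_disk = (
            spec.cluster_in_disk
            if spec.cluster_in_disk is not None
            else spec.cluster_type == "GM1"
        )
        if spec.cluster_type and leaflet == spec.cluster_leaflet:
            for ci, size in enumerate(spec.cluster_sizes):
                if in_disk:
                    center = np.array([cx, cy]) + np.array([3.2 * ci, 0.0])
                else:  # background-adjacent, offset from the centre region
                    center = np.array([cx, cy]) + np.array(
                        [0.0, -(spec.box_xy / 2.0 - 1.5) + 3.2 * ci]
                    )
                offs = _cluster_offsets(size, spec.cluster_spacing)
                members = center + offs
                cluster_positions.append(members)
            all_members = np.vstack(cluster_positions)
            d2 = np.min(
                np.linalg.norm(sites[:, None, :] - all_members[None, :, :], axis=2),
                axis=1,
            )
            keep = d2 > 0.8
            sites, r = sites[keep], r[keep]

        # budget split: odd counts put the extra lipid in the top leaflet
        def _half(n: int) -> int:
            return n // 2 + (n % 2 if leaflet == TOP else 0)

        n_dppc, n_dlpc = _half(spec.n_dppc), _half(spec.n_dlpc)
        n_chol = _half(spec.n_chol)
        n_pairs = spec.lod_pairs
        n_dppc_core = n_dppc - n_pairs
        n_dlpc_bg = n_dlpc - n_pairs
        if n_dppc_core < 0 or n_dlpc_bg < 0:
            raise SpecError("lod_pairs exceed the per-leaflet PC budgets")

        cursor = 0

        def _take(n: int, min_r: float) -> np.ndarray:
            nonlocal cursor
            while cursor < len(sites) and r[cursor] < min_r:
                cursor += 1
            if cursor + n > len(sites):
                raise SpecError("lipids do not fit the lattice: enlarge the box")
            out = sites[cursor : cursor + n]
            cursor += n
            return out

        core = _take(n_dppc_core, 0.0)
        r1 = float(r[cursor - 1]) if n_dppc_core else 0.0
        pair_sites = _take(n_pairs, r1 + spec.gap) if n_pairs else np.empty((0, 2))
        r2 = float(r[cursor - 1]) if n_pairs else r1
        background = _take(n_dlpc_bg, r2 + spec.gap)

        ai = iter(azi_cycle * 1000)

        def _add_pc(xy, mtype: MoleculeType, region: str) -> int:
            head = np.array([xy[0], xy[1], z_head])
            tilt = spec.tilt_by_region[region]
            names, coords = _pc_coords(head, sign, tilt, (next(ai), next(ai)), nb, sp)
            mid = b.add_molecule(mtype, mtype.value, names, coords)
            gt.leaflets[mid] = leaflet
            region_of[mid] = region
            return mid

        core_mids = [_add_pc(xy, MoleculeType.DPPC, LO) for xy in core]
        for mid in core_mids:
            gt.pc_domains[mid] = LO
        for xy in pair_sites:
            m1 = _add_pc(xy, MoleculeType.DPPC, LOD)
            m2 = _add_pc(xy + np.array([spec.pair_offset, 0.0]), MoleculeType.DLPC, LOD)
            gt.pc_domains[m1] = LOD
            gt.pc_domains[m2] = LOD
        bg_mids = [_add_pc(xy, MoleculeType.DLPC, LD) for xy in background]
        for mid in bg_mids:
            gt.pc_domains[mid] = LD

        # CHOL companions: a short rod 0.3 nm beside a host PC, inheriting
        # the host's domain by the nearest-PC rule
        hosts = core_mids + bg_mids
        host_regions = [LO] * len(core_mids) + [LD] * len(bg_mids)
        if hosts:
            for k in range(n_chol):
                h = k % len(hosts)
                lap = (k // len(hosts) + 1) * 0.3  # stack offsets if CHOL > hosts
                host_head = b.positions()[
                    [i for i, at in enumerate(b.atoms) if at.molecule_id == hosts[h]][0]
                ]
                head = host_head + np.array([0.0, lap, 0.0])
                coords = np.vstack(
                    [head, head + [0, 0, sign * 0.3], head + [0, 0, sign * 0.6]]
                )
                mid = b.add_molecule(
                    MoleculeType.CHOL, "CHOL", ["ROH", "R1", "R2"], coords
                )
                gt.leaflets[mid] = leaflet
                gt.chol_domains[mid] = host_regions[h]
                region_of[mid] = host_regions[h]

        # cluster lipids
        if spec.cluster_type and leaflet == spec.cluster_leaflet:
            ctype = MoleculeType(spec.cluster_type)
            gt.clusters.setdefault(ctype.value, [])
            gt.cluster_context.setdefault(ctype.value, [])
            for members in cluster_positions:
                mids = []
                for xy in members:
                    head = np.array([xy[0], xy[1], z_head])
                    if ctype is MoleculeType.GM1:
                        names = ["GM1H", "GH1", "GH2"] + _chain_names(nb, "A") + _chain_names(nb, "B")
                        _, pc = _pc_coords(head, sign, spec.tilt_by_region[LO],
                                           (next(ai), next(ai)), nb, sp)
                        stack = np.vstack(
                            [head, head - [0, 0, sign * 0.25], head - [0, 0, sign * 0.5]]
                        )
                        coords = np.vstack([stack, pc[1:]])
                    else:
                        names, coords = _pc_coords(
                            head, sign, spec.tilt_by_region[LOD], (next(ai), next(ai)), nb, sp
                        )
                    mid = b.add_molecule(ctype, ctype.value, names, coords)
                    gt.leaflets[mid] = leaflet
                    mids.append(mid)
                gt.clusters[ctype.value].append(mids)
                # one explicit PC neighbor 0.4 nm east of the cluster pins
                # the cluster's domain context (Lo for GM1 in the ordered
                # disk, Ld for POPS in the background)
                east = members[np.argmax(members[:, 0])]
                if in_disk:  # surrounded by the ordered DPPC disk
                    ctx_mid = _add_pc(east + np.array([0.4, 0.0]), MoleculeType.DPPC, LO)
                    gt.pc_domains[ctx_mid] = LO
                    gt.cluster_context[ctype.value].append(LO)
                else:
                    ctx_mid = _add_pc(east + np.array([0.4, 0.0]), MoleculeType.DLPC, LD)
                    gt.pc_domains[ctx_mid] = LD
                    gt.cluster_context[ctype.value].append(LD)

    meta = {"z_top": z_mid + half, "z_mid": z_mid, "center": (cx, cy)}
    return b, gt, meta


def _add_solvent(b: _Builder, spec: SyntheticSpec, z_top: float) -> None:
    if spec.water:
        n = max(1, int(spec.box_xy // spec.water_spacing))
        xs = (np.arange(n) + 0.5) * spec.water_spacing
        for layer in range(spec.water_layers):
            z = z_top + 0.4 + layer * spec.water_spacing
            for x in xs:
                for y in xs:
                    b.add_molecule(
                        MoleculeType.WATER, "W", ["W"], np.array([[x, y, z]])
                    )
    for k in range(spec.n_ions):
        z = z_top + 0.4 + spec.water_layers * spec.water_spacing
        b.add_molecule(
            MoleculeType.ION, "ION", ["NA"],
            np.array([[(k + 0.5) * spec.box_xy / max(spec.n_ions, 1), 0.5, z]]),
        )


def _finish_topology(b: _Builder, spec: SyntheticSpec) -> Topology:
    sequences = {
        chr(ord("A") + c): spec.sequence for c in range(spec.protein_chains)
    } if any(a.molecule_type is MoleculeType.PROTEIN for a in b.atoms) else {}
    return Topology(
        b.atoms,
        lipid_reference_atoms=DEFAULT_LIPID_REFERENCE_ATOMS,
        protein_sequences=sequences,
    )


def generate_raft_frame(
    spec: SyntheticSpec, seed: int
) -> tuple[Topology, Frame, GroundTruth]:
    """One membrane-only frame (no protein) with ground-truth sidecar."""
    b, gt, meta = _build_membrane(spec)
    _add_solvent(b, spec, meta["z_top"])
    topo = _finish_topology(b, spec)
    rng = np.random.default_rng(seed)
    pos = b.positions() + rng.normal(0.0, spec.jitter_sigma, (len(b.atoms), 3))
    frame = Frame(pos, np.array([spec.box_xy, spec.box_xy, spec.box_z]), 0.0)
    return topo, frame, gt


def _protein_base_pose(spec: SyntheticSpec) -> np.ndarray:
    """Relative serpentine pose of one chain (L x 3), centred at origin."""
    L = len(spec.sequence)
    per_row = 10
    rel = np.zeros((L, 3))
    for i in range(L):
        row, col = divmod(i, per_row)
        x = col * 0.35 if row % 2 == 0 else (per_row - 1 - col) * 0.35
        rel[i] = [x, row * 0.45, 0.0]
    rel[:, :2] -= rel[:, :2].mean(axis=0)
    return rel


def _bound_pose(
    spec: SyntheticSpec,
    membrane_heads: np.ndarray,
    cluster_heads: np.ndarray | None,
    z_top: float,
    center: tuple[float, float],
) -> np.ndarray:
    """Bound-state coordinates for all chains (chains side by side in y)."""
    rel = _protein_base_pose(spec)
    L = rel.shape[0]
    chains = []
    for c in range(spec.protein_chains):
        xy = rel[:, :2] + np.array(center) + np.array([0.0, 1.9 * c - 0.95 * (spec.protein_chains - 1)])
        z = np.full(L, z_top + 0.35)
        pose = np.column_stack([xy, z])
        if spec.binding_mode == "anchored":
            for ridx in spec.anchor_residues:
                i = ridx - 1
                # bury the anchor just below the nearest headgroup
                d = np.linalg.norm(membrane_heads[:, :2] - pose[i, :2], axis=1)
                target = membrane_heads[int(np.argmin(d))]
                pose[i] = target + np.array([0.05, 0.05, -0.30])
        else:  # N-terminal (residues 1-12) contact mode over a cluster
            ref = cluster_heads if cluster_heads is not None and len(cluster_heads) else membrane_heads
            for i in range(min(12, L)):
                d = np.linalg.norm(ref[:, :2] - pose[i, :2], axis=1)
                target = ref[int(np.argmin(d))]
                pose[i] = target + np.array([0.05, 0.05, +0.15])
            if L >= 26:
                # residue 26 lifted far enough that its lipid distance
                # exceeds any lateral offset of the remaining residues
                pose[25, 2] = z_top + 2.2
        chains.append(pose)
    return np.vstack(chains)


def generate_binding_trajectory(
    spec: SyntheticSpec, seed: int
) -> tuple[Trajectory, GroundTruth]:
    """Membrane + oligomer trajectory with a prescribed abrupt binding event.

    The oligomer starts >= ``start_height`` above the top headgroup plane,
    random-walks laterally (identically across replicates; replicates 2/3
    are x-shifted by +2/-2 nm), and from the first frame at or after
    ``binding_time`` adopts the bound pose: anchor residues buried below
    the headgroup plane, every other residue at or above it.
    """
    b, gt, meta = _build_membrane(spec)
    z_top, center = meta["z_top"], meta["center"]

    # protein chains (1 bead per residue)
    L = len(spec.sequence)
    for c in range(spec.protein_chains):
        chain_id = chr(ord("A") + c)
        names = ["BB"] * L
        resnames = [ONE_TO_THREE[x] for x in spec.sequence]
        b.mol_counter += 1
        mid = b.mol_counter
        for i in range(L):
            b.atoms.append(
                Atom(
                    atom_id=len(b.atoms) + 1,
                    atom_name=names[i],
                    residue_index=i + 1,
                    residue_name=resnames[i],
                    molecule_id=mid,
                    molecule_type=MoleculeType.PROTEIN,
                    chain_id=chain_id,
                )
            )
            b.pos.append(np.zeros(3))
    _add_solvent(b, spec, z_top)
    topo = _finish_topology(b, spec)

    base = b.positions()
    protein_rows = topo.protein_indices()
    lipid_head_rows = np.array(
        sorted(topo.headgroup_indices().values()), dtype=np.intp
    )
    top_heads = base[
        [i for m, i in topo.headgroup_indices().items() if gt.leaflets.get(m) == TOP]
    ]
    cluster_heads = None
    if spec.cluster_type and spec.cluster_type in gt.clusters:
        rows = [
            topo.headgroup_index(m)
            for cl in gt.clusters[spec.cluster_type]
            for m in cl
        ]
        cluster_heads = base[rows]

    bound = _bound_pose(spec, top_heads, cluster_heads, z_top, center)
    rel = np.vstack([_protein_base_pose(spec)] * spec.protein_chains)

    mem_rng = np.random.default_rng(seed)
    walk_rng = np.random.default_rng(seed + 7919)  # shared by all replicates
    x_off = REPLICATE_X_OFFSETS[spec.replicate]

    frames = []
    t_bind_true = None
    steps = walk_rng.normal(0.0, 0.05, (spec.n_frames, 2)).cumsum(axis=0)
    for i in range(spec.n_frames):
        t = i * spec.dt
        pos = base + mem_rng.normal(0.0, spec.jitter_sigma, base.shape)
        if t < spec.binding_time:
            cxy = np.array(center) + np.array([x_off, 0.0]) + steps[i]
            z0 = z_top + spec.start_height + 0.2 * math.sin(0.13 * i)
            pose = rel + np.array([cxy[0], cxy[1], z0])
            pos[protein_rows] = pose + mem_rng.normal(0.0, spec.jitter_sigma, pose.shape)
        else:
            if t_bind_true is None:
                t_bind_true = t
            pos[protein_rows] = bound + mem_rng.normal(
                0.0, spec.jitter_sigma, bound.shape
            )
        frames.append(Frame(pos, np.array([spec.box_xy, spec.box_xy, spec.box_z]), t))

    gt.binding_time = t_bind_true
    gt.binding_leaflet = TOP
    if spec.binding_mode == "anchored":
        gt.anchor_residues = tuple(spec.anchor_residues)
    else:
        gt.contact_residues = tuple(range(1, min(12, L) + 1))
    return Trajectory(topo, frames, "CG"), gt


def generate_tilted_chains(
    tilt_deg: float,
    n_lipids: int = 32,
    n_beads: int = 6,
    spacing: float = 0.3,
    box_xy: float = 12.0,
    seed: int = 0,
    jitter_sigma: float = 0.0,
    n_frames: int = 1,
) -> tuple[Topology, list[Frame], float]:
    """Straight bead rods at a fixed cone angle with uniform azimuths.

    The analytic order parameter S = (3 cos^2 theta - 1)/2 is returned as
    ground truth (exact when jitter is zero).
    """
    if not 0.0 <= tilt_deg <= 90.0:
        raise SpecError("cone angle must lie in [0, 90] degrees")
    b = _Builder()
    rng = np.random.default_rng(seed)
    n_side = int(math.ceil(math.sqrt(n_lipids)))
    a = box_xy / n_side
    k = 0
    for i in range(n_side):
        for j in range(n_side):
            if k >= n_lipids:
                break
            head = np.array([(i + 0.5) * a, (j + 0.5) * a, 6.0])
            phi = rng.uniform(0.0, 2 * math.pi)
            names, coords = _pc_coords(
                head, -1.0, tilt_deg, (phi, phi + math.pi / 2), n_beads, spacing
            )
            b.add_molecule(MoleculeType.DPPC, "DPPC", names, coords)
            k += 1
    refs = dict(DEFAULT_LIPID_REFERENCE_ATOMS)
    refs[MoleculeType.DPPC] = (
        "PO4",
        (tuple(_chain_names(n_beads, "A")), tuple(_chain_names(n_beads, "B"))),
    )
    topo = Topology(b.atoms, lipid_reference_atoms=refs)
    base = b.positions()
    frames = []
    for i in range(n_frames):
        pos = base + rng.normal(0.0, jitter_sigma, base.shape) if jitter_sigma else base.copy()
        frames.append(Frame(pos, np.array([box_xy, box_xy, 12.0]), float(i)))
    theta = math.radians(tilt_deg)
    s_true = 0.5 * (3.0 * math.cos(theta) ** 2 - 1.0)
    return topo, frames, s_true


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    transition = np.asarray(transition, dtype=np.float64)
    if transition.shape != (8, 8) or not np.allclose(transition.sum(axis=1), 1.0):
        raise SpecError("transition matrix must be 8x8 row-stochastic")
    w, v = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def generate_ss_matrix(
    n_residues: int,
    n_frames: int,
    transition: np.ndarray,
    seed: int = 0,
) -> tuple[SSMatrix, GroundTruth]:
    """Per-residue independent Markov chains over the 8 DSSP codes."""
    transition = np.asarray(transition, dtype=np.float64)
    pi = stationary_distribution(transition)
    rng = np.random.default_rng(seed)
    codes = np.empty((n_residues, n_frames), dtype="<U1")
    cum = transition.cumsum(axis=1)
    for r in range(n_residues):
        state = int(rng.choice(8, p=pi))
        codes[r, 0] = SS_CODES[state]
        u = rng.random(n_frames - 1)
        for f in range(1, n_frames):
            state = int(np.searchsorted(cum[state], u[f - 1], side="right"))
            state = min(state, 7)
            codes[r, f] = SS_CODES[state]
    cat_pi = {c: 0.0 for c in CATEGORIES}
    for code, p in zip(SS_CODES, pi):
        cat_pi[CODE_TO_CATEGORY[code]] += float(p)
    gt = GroundTruth(stationary=cat_pi)
    return SSMatrix(codes), gt


def uniform_transition_matrix() -> np.ndarray:
    return np.full((8, 8), 1.0 / 8.0)


def co_raft_counts(scale: float = 1 / 12) -> dict[str, int]:
    """CO-raft composition (828:540:576 DPPC:DLPC:CHOL) scaled down."""
    from .config import CO_RAFT_COUNTS

    return {t.value: round(n * scale) for t, n in CO_RAFT_COUNTS.items()}
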