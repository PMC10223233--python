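"""Membrane-disruption metrics: thickness, area per lipid, chain order.

Per-lipid bilayer thickness uses the opposing-leaflet headgroup plane
within a lateral (xy, minimum-image) radius; area per lipid is the cell
area of a periodic planar tessellation of headgroup reference points; the
acyl-chain orientational order parameter S(k) = (3<cos^2 theta> - 1)/2
measures the tilt of the axis through carbons k-1 and k+1 against the
bilayer normal (the fixed z-axis of these planar membranes).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon

from .config import THICKNESS_LATERAL_RADIUS, MoleculeType
from .core import Frame, Topology, replicate_mean_sem, warn
from .errors import RaftbindError, SelectionError
from .nanodomains import BOTTOM, TOP, LeafletLabel


def bilayer_thickness(
    frame: Frame,
    topology: Topology,
    leaflets: LeafletLabel,
    selection: list[int] | None = None,
    lateral_radius: float = THICKNESS_LATERAL_RADIUS,
) -> dict[int, float]:
    """Per-lipid leaflet-to-leaflet thickness (nm).

    thickness(lipid) = |z_ref(lipid) - <z_ref of opposing-leaflet lipids
    within lateral_radius in xy (minimum image)>|.  Lipids without an
    opposing neighbor inside the radius are skipped with a warning.
    """
    heads = topology.headgroup_indices()
    top_ids = [m for m in heads if leaflets.labels.get(m) == TOP]
    bot_ids = [m for m in heads if leaflets.labels.get(m) == BOTTOM]
    if not top_ids or not bot_ids:
        raise SelectionError("thickness requires both leaflets populated")
    pos = frame.positions
    box_xy = frame.box[:2]
    coords = {m: pos[heads[m]] for m in heads}
    opposing = {TOP: bot_ids, BOTTOM: top_ids}
    targets = selection if selection is not None else list(heads)
    out: dict[int, float] = {}
    skipped = 0
    for mid in targets:
        leaf = leaflets.labels.get(mid)
        if leaf is None:
            continue
        other = opposing[leaf]
        other_xy = np.array([coords[m][:2] for m in other])
        d_xy = other_xy - coords[mid][:2]
        d_xy -= box_xy * np.round(d_xy / box_xy)
        near = np.linalg.norm(d_xy, axis=1) <= lateral_radius
        if not near.any():
            skipped += 1
            continue
        z_opp = np.array([coords[m][2] for m in other])[near].mean()
        out[mid] = float(abs(coords[mid][2] - z_opp))
    if skipped:
        warn(f"{skipped} lipid(s) had no opposing-leaflet neighbor within "
             f"{lateral_radius} nm and were skipped")
    return out


def area_per_lipid(
    frame: Frame,
    topology: Topology,
    leaflets: LeafletLabel,
    leaflet: str = TOP,
    selection: list[int] | None = None,
) -> dict[int, float]:
    """Per-lipid tessellation cell area (nm^2) within one leaflet.

    Headgroup reference points are projected to xy and tessellated under
    periodic boundaries (3x3 image tiling, keeping the central copy's
    cells); cell areas sum exactly to the lateral box area.
    """
    heads = topology.headgroup_indices()
    ids = [m for m in heads if leaflets.labels.get(m) == leaflet]
    if len(ids) < 3:
        raise SelectionError("area per lipid needs at least 3 lipids in the leaflet")
    lx, ly = float(frame.box[0]), float(frame.box[1])
    pts = frame.positions[[heads[m] for m in ids], :2].copy()
    pts[:, 0] %= lx
    pts[:, 1] %= ly
    if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
        raise RaftbindError("degenerate (colinear) headgroup projection")
    images = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            images.append(pts + np.array([dx * lx, dy * ly]))
    tiled = np.vstack(images)
    central_offset = 4 * len(ids)  # (dx,dy)=(0,0) block
    vor = Voronoi(tiled)
    out: dict[int, float] = {}
    for k, mid in enumerate(ids):
        region = vor.regions[vor.point_region[central_offset + k]]
        if -1 in region or len(region) == 0:
            raise RaftbindError("unbounded tessellation cell; degenerate input")
        out[mid] = float(Polygon(vor.vertices[region]).area)
    if selection is not None:
        out = {m: a for m, a in out.items() if m in selection}
    return out


@dataclass
class OrderProfile:
    """Chain order parameter vs carbon index for one lipid type/group."""

    lipid_type: str
    group: str
    carbons: np.ndarray        # 1-based carbon/bead index (2..n-1)
    s: np.ndarray
    sem: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lipid_type": self.lipid_type,
                "group": self.group,
                "carbon": self.carbons,
                "S": self.s,
                "sem": self.sem,
            }
        )


def _wrap(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def chain_order_parameter(
    frames: list[Frame],
    topology: Topology,
    lipid_ids: list[int],
    lipid_type: MoleculeType | str,
    group: str = "all",
) -> OrderProfile:
    """S(k) = (3<cos^2 theta_k> - 1)/2 averaged over frames, lipids, chains.

    The molecular axis at carbon k is the vector from carbon k-1 to k+1;
    theta is its angle to the z-axis.  Chains need at least 3 carbons.
    Interior carbons are indexed 2..n-1 (1-based).  For coarse-grained
    lipids "carbon" means chain bead.
    """
    tname = MoleculeType(lipid_type).value
    ids = [m for m in lipid_ids if topology.molecule_type_of(m).value == tname]
    if not ids:
        raise SelectionError(f"no {tname} lipids in the selection")
    chain_sets = {m: topology.chain_carbon_indices(m) for m in ids}
    n_carbons = len(next(iter(chain_sets.values()))[0])
    if n_carbons < 3:
        raise RaftbindError("chains need at least 3 carbons for an order profile")
    n_interior = n_carbons - 2
    samples: list[list[float]] = [[] for _ in range(n_interior)]
    for frame in frames:
        box = frame.box
        for m in ids:
            for chain in chain_sets[m]:
                if chain.size < 3:
                    continue
                p = frame.positions[chain]
                for k in range(1, chain.size - 1):
                    axis = _wrap(p[k + 1] - p[k - 1], box)
                    norm = np.linalg.norm(axis)
                    if norm == 0:
                        continue
                    cos2 = (axis[2] / norm) ** 2
                    samples[k - 1].append(0.5 * (3.0 * cos2 - 1.0))
    s = np.array([np.mean(v) if v else np.nan for v in samples])
    sem = np.array(
        [
            (np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
            for v in samples
        ]
    )
    return OrderProfile(tname, group, np.arange(2, n_carbons), s, sem)


def aggregate_order_profiles(profiles: list[OrderProfile]) -> OrderProfile:
    """Replicate mean +- SEM of per-replicate order profiles."""
    s = np.stack([p.s for p in profiles])
    stats = [replicate_mean_sem(s[:, k]) for k in range(s.shape[1])]
    first = profiles[0]
    return OrderProfile(
        first.lipid_type,
        first.group,
        first.carbons,
        np.array([m.mean for m in stats]),
        np.array([m.sem for m in stats]),
    )


def annular_vs_nonannular(
    annular: OrderProfile, nonannular: OrderProfile
) -> pd.DataFrame:
    """Per-carbon difference S_annular - S_nonannular with propagated SEM."""
    if not np.array_equal(annular.carbons, nonannular.carbons):
        raise RaftbindError("profiles have different carbon axes")
    return pd.DataFrame(
        {
            "lipid_type": annular.lipid_type,
            "carbon": annular.carbons,
            "S_annular": annular.s,
            "S_nonannular": nonannular.s,
            "delta_S": annular.s - nonannular.s,
            "sem": np.sqrt(annular.sem**2 + nonannular.sem**2),
        }
    )


def grouped_metric_comparison(
    metric_by_group: dict[str, dict[int, float]]
) -> pd.DataFrame:
    """Group means +- SEM for thickness/APL dictionaries, one row per group.

    Absent groups are simply not present in the output (reported as absent,
    never as zero).
    """
    rows = []
    for group, values in metric_by_group.items():
        if not values:
            continue
        ms = replicate_mean_sem(values.values())
        rows.append({"group": group, "mean": ms.mean, "sem": ms.sem, "n": ms.n})
    return pd.DataFrame(rows)
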