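"""Periodic-boundary distance machinery.

Minimum-image metric for orthorhombic boxes, grid-accelerated neighbor
search, group minimum distances and contact counts.  The heavy lifting is
done by MDAnalysis' distance kernels; this module owns the selection
semantics and the boundary conventions (contacts use a strict ``<`` cutoff,
shell/threshold membership elsewhere uses ``<=``).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from MDAnalysis.lib import distances as _mdadist

from .core import Frame
from .errors import QueryError, SelectionError


@dataclass(frozen=True)
class AtomSelection:
    """A named, ordered set of atom indices."""

    name: str
    indices: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "indices", np.asarray(self.indices, dtype=np.intp).ravel()
        )

    def __len__(self) -> int:
        return int(self.indices.size)

    def require_nonempty(self) -> None:
        if len(self) == 0:
            raise SelectionError(f"selection {self.name!r} is empty")


@dataclass(frozen=True)
class NeighborQuery:
    """Parameters of a periodic neighbor search."""

    cutoff: float
    cell_edge: float | None = None
    periodic: tuple[bool, bool, bool] = (True, True, True)

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise QueryError("cutoff must be positive")
        if self.cell_edge is not None and self.cell_edge < self.cutoff:
            raise QueryError("cell edge must be >= cutoff")


def _mda_box(box: np.ndarray) -> np.ndarray:
    return np.array([box[0], box[1], box[2], 90.0, 90.0, 90.0], dtype=np.float64)


def min_image_distance(p, q, box) -> float:
    """Euclidean distance between two points under the minimum-image convention."""
    box = np.asarray(box, dtype=np.float64)
    d = np.asarray(p, dtype=np.float64) - np.asarray(q, dtype=np.float64)
    d -= box * np.round(d / box)
    return float(np.linalg.norm(d))


def pairwise_distances(
    pos_a: np.ndarray, pos_b: np.ndarray, box: np.ndarray
) -> np.ndarray:
    """All-pairs minimum-image distance matrix (len(A) x len(B))."""
    return _mdadist.distance_array(
        np.ascontiguousarray(pos_a, dtype=np.float64),
        np.ascontiguousarray(pos_b, dtype=np.float64),
        box=_mda_box(np.asarray(box, dtype=np.float64)),
    )


def group_min_distance(
    a: AtomSelection, b: AtomSelection, frame: Frame
) -> tuple[float, tuple[int, int]]:
    """Smallest pairwise minimum-image distance between two atom groups.

    Returns the distance and one achieving ``(atom_index_a, atom_index_b)``
    pair (the lexicographically first achieving pair, for determinism).
    """
    a.require_nonempty()
    b.require_nonempty()
    dmat = pairwise_distances(
        frame.positions[a.indices], frame.positions[b.indices], frame.box
    )
    flat = int(np.argmin(dmat))
    i, j = np.unravel_index(flat, dmat.shape)
    return float(dmat[i, j]), (int(a.indices[i]), int(b.indices[j]))


def count_contacts(
    a: AtomSelection, b: AtomSelection, frame: Frame, cutoff: float
) -> int:
    """Number of atom pairs (a in A, b in B) strictly within ``cutoff``."""
    a.require_nonempty()
    b.require_nonempty()
    if cutoff <= 0:
        raise QueryError("cutoff must be positive")
    if cutoff <= 0.5 * float(np.min(frame.box)):
        pairs, dists = _capped(frame, a, b, cutoff)
        return int(np.count_nonzero(dists < cutoff))
    dmat = pairwise_distances(
        frame.positions[a.indices], frame.positions[b.indices], frame.box
    )
    return int(np.count_nonzero(dmat < cutoff))


def _capped(frame: Frame, a: AtomSelection, b: AtomSelection, cutoff: float):
    pairs, dists = _mdadist.capped_distance(
        np.ascontiguousarray(frame.positions[a.indices], dtype=np.float64),
        np.ascontiguousarray(frame.positions[b.indices], dtype=np.float64),
        max_cutoff=cutoff,
        box=_mda_box(frame.box),
        return_distances=True,
    )
    return pairs, np.asarray(dists, dtype=np.float64)


def neighbor_pairs(
    frame: Frame,
    a: AtomSelection,
    b: AtomSelection,
    query: NeighborQuery,
) -> tuple[np.ndarray, np.ndarray]:
    """All (i, j) atom-index pairs with minimum-image distance <= cutoff.

    Pairs are returned sorted by (i, j) so the order is deterministic.
    Raises :class:`QueryError` when the cutoff exceeds half the smallest
    periodic box edge (minimum image is ambiguous there; callers should
    fall back to :func:`pairwise_distances`).
    """
    a.require_nonempty()
    b.require_nonempty()
    half = 0.5 * float(np.min(frame.box))
    if query.cutoff > half:
        raise QueryError(
            f"cutoff {query.cutoff} nm exceeds half the smallest box edge "
            f"({half} nm); use brute-force pairwise_distances"
        )
    pairs, dists = _capped(frame, a, b, query.cutoff)
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.intp), np.empty(0)
    keep = dists <= query.cutoff
    pairs, dists = pairs[keep], dists[keep]
    out = np.column_stack([a.indices[pairs[:, 0]], b.indices[pairs[:, 1]]])
    order = np.lexsort((out[:, 1], out[:, 0]))
    return out[order].astype(np.intp), dists[order]


def per_molecule_min_distance(
    frame: Frame,
    ref: AtomSelection,
    mol_atom_indices: np.ndarray,
    mol_ids: np.ndarray,
) -> dict[int, float]:
    """Minimum distance from each molecule (grouped atoms) to a reference group.

    ``mol_atom_indices``/``mol_ids`` are parallel arrays mapping atoms to
    their molecule id; returns molecule_id -> min distance (nm).
    """
    ref.require_nonempty()
    if mol_atom_indices.size == 0:
        return {}
    dmat = pairwise_distances(
        frame.positions[mol_atom_indices], frame.positions[ref.indices], frame.box
    )
    per_atom = dmat.min(axis=1)
    out: dict[int, float] = {}
    for mid in np.unique(mol_ids):
        out[int(mid)] = float(per_atom[mol_ids == mid].min())
    return out
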