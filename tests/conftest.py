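"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's minimum-image formula and
neighbor search: distances are computed by explicit enumeration of the 27
periodic images, so agreement is a genuine two-route check.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from raftbind.core import Frame
from raftbind.synthetic import SyntheticSpec, generate_binding_trajectory, generate_raft_frame


# ---------------------------------------------------------------- oracles
_SHIFTS = np.array(
    [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=np.float64,
)


def brute_distance_matrix(pos_a: np.ndarray, pos_b: np.ndarray, box) -> np.ndarray:
    """All-pairs periodic distances by explicit 27-image enumeration."""
    box = np.asarray(box, dtype=np.float64)
    best = None
    for s in _SHIFTS:
        d = np.linalg.norm(
            pos_a[:, None, :] - (pos_b[None, :, :] + (s * box)[None, None, :]), axis=2
        )
        best = d if best is None else np.minimum(best, d)
    return best


def brute_min_distance(pos_a, pos_b, box) -> float:
    return float(brute_distance_matrix(np.atleast_2d(pos_a), np.atleast_2d(pos_b), box).min())


def brute_count_contacts(pos_a, pos_b, box, cutoff) -> int:
    return int((brute_distance_matrix(pos_a, pos_b, box) < cutoff).sum())


def brute_pairs(pos_a, pos_b, box, cutoff) -> set[tuple[int, int]]:
    d = brute_distance_matrix(pos_a, pos_b, box)
    return {(int(i), int(j)) for i, j in zip(*np.where(d <= cutoff))}


# ---------------------------------------------------------------- fixtures
@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_raft():
    """Membrane-only frame with separated domains, a GM1 cluster and ground truth."""
    spec = SyntheticSpec(cluster_type="GM1", cluster_sizes=(12,), box_xy=14.0)
    topo, frame, gt = generate_raft_frame(spec, seed=11)
    return topo, frame, gt


@pytest.fixture(scope="session")
def lod_raft():
    """Membrane with a mixed DPPC/DLPC boundary ring (Lod ground truth)."""
    spec = SyntheticSpec(lod_pairs=6, box_xy=14.0)
    topo, frame, gt = generate_raft_frame(spec, seed=13)
    return topo, frame, gt


@pytest.fixture(scope="session")
def binding_traj():
    """60-frame binding trajectory, anchors 16/26, binding at t = 20 ns."""
    spec = SyntheticSpec(n_frames=60, binding_time=20.0)
    traj, gt = generate_binding_trajectory(spec, seed=3)
    return traj, gt


@pytest.fixture(scope="session")
def gm_binding_traj():
    """GM-raft-like trajectory: N-terminal contact mode over a GM1 cluster."""
    spec = SyntheticSpec(
        cluster_type="GM1",
        cluster_sizes=(14,),
        box_xy=14.0,
        binding_mode="nterm",
        n_frames=30,
        binding_time=10.0,
    )
    traj, gt = generate_binding_trajectory(spec, seed=2)
    return traj, gt


def toy_frame(positions, box=(10.0, 10.0, 10.0), time=0.0) -> Frame:
    return Frame(np.asarray(positions, dtype=np.float64), np.asarray(box), time)
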