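"""Thickness, area per lipid, and acyl-chain order parameters."""
import math

import numpy as np
import pytest

from raftbind.config import MoleculeType
from raftbind.core import Frame
from raftbind.errors import SelectionError
from raftbind.nanodomains import assign_leaflets
from raftbind.structure import (
    aggregate_order_profiles,
    annular_vs_nonannular,
    area_per_lipid,
    bilayer_thickness,
    chain_order_parameter,
    grouped_metric_comparison,
)
from raftbind.synthetic import (
    SyntheticSpec,
    generate_raft_frame,
    generate_tilted_chains,
)


class TestThickness:
    def test_flat_slab(self, small_raft):
        topo, frame, gt = small_raft
        leaf = assign_leaflets(frame, topo)
        th = bilayer_thickness(frame, topo, leaf)
        vals = np.array(list(th.values()))
        assert vals == pytest.approx(gt.thickness, abs=0.1)

    def test_translation_invariance(self, small_raft):
        topo, frame, gt = small_raft
        leaf = assign_leaflets(frame, topo)
        t0 = bilayer_thickness(frame, topo, leaf)
        moved = Frame(frame.positions + [0, 0, 3.0], frame.box + 6.0, frame.time)
        leaf2 = assign_leaflets(moved, topo)
        t1 = bilayer_thickness(moved, topo, leaf2)
        for m in t0:
            assert t1[m] == pytest.approx(t0[m], abs=1e-9)

    def test_prescribed_plane_separation(self):
        spec = SyntheticSpec(thickness=3.8, jitter_sigma=0.0, box_xy=10.0,
                             n_dppc=20, n_dlpc=16, n_chol=0, water=False, n_ions=0)
        topo, frame, _ = generate_raft_frame(spec, 0)
        leaf = assign_leaflets(frame, topo)
        th = bilayer_thickness(frame, topo, leaf)
        assert np.array(list(th.values())) == pytest.approx(3.8, abs=1e-9)


class TestAreaPerLipid:
    def _lattice_system(self, n_side, box):
        spec = SyntheticSpec(
            n_dppc=2 * n_side * n_side, n_dlpc=0, n_chol=0, box_xy=box,
            lattice_spacing=box / n_side, jitter_sigma=0.0, gap=0.0,
            water=False, n_ions=0,
        )
        return generate_raft_frame(spec, 0)

    def test_regular_lattice_cells(self):
        topo, frame, _ = self._lattice_system(4, 4.0)
        leaf = assign_leaflets(frame, topo)
        apl = area_per_lipid(frame, topo, leaf, "TOP")
        assert len(apl) == 16
        assert np.array(list(apl.values())) == pytest.approx(1.0, abs=1e-6)

    def test_conservation_random(self, small_raft):
        topo, frame, _ = small_raft
        leaf = assign_leaflets(frame, topo)
        for side in ("TOP", "BOTTOM"):
            apl = area_per_lipid(frame, topo, leaf, side)
            assert sum(apl.values()) == pytest.approx(
                frame.box[0] * frame.box[1], rel=1e-6
            )

    def test_too_few_lipids_rejected(self):
        topo, frame, _ = self._lattice_system(4, 4.0)
        leaf = assign_leaflets(frame, topo)
        leaf.labels = {m: ("TOP" if i < 2 else "BOTTOM")
                       for i, m in enumerate(leaf.labels)}
        with pytest.raises(SelectionError):
            area_per_lipid(frame, topo, leaf, "TOP")


class TestOrderParameter:
    @pytest.mark.parametrize(
        "tilt,expected",
        [(0.0, 1.0), (90.0, -0.5), (54.7356, 0.0)],
    )
    def test_closed_form_limits(self, tilt, expected):
        topo, frames, s_true = generate_tilted_chains(tilt, n_lipids=9)
        ids = [int(m) for m in topo.lipid_molecule_ids()]
        prof = chain_order_parameter(frames, topo, ids, "DPPC")
        assert s_true == pytest.approx(expected, abs=1e-6)
        assert prof.s == pytest.approx(expected, abs=1e-6)

    def test_fixed_cone_angle(self):
        topo, frames, s_true = generate_tilted_chains(30.0, n_lipids=16)
        ids = [int(m) for m in topo.lipid_molecule_ids()]
        prof = chain_order_parameter(frames, topo, ids, "DPPC")
        assert prof.s == pytest.approx(s_true, abs=1e-9)
        assert np.array_equal(prof.carbons, np.arange(2, 6))

    def test_isotropic_axes_average_to_zero(self):
        # Monte-Carlo oracle: S of isotropically drawn axes is 0 +- 3 sigma
        rng = np.random.default_rng(5)
        n = 10_000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        s_samples = 0.5 * (3.0 * u[:, 2] ** 2 - 1.0)
        s = s_samples.mean()
        sigma = s_samples.std(ddof=1) / math.sqrt(n)
        assert abs(s) < 3 * sigma + 0.02

    def test_bounds_invariant(self, binding_traj):
        traj, _ = binding_traj
        topo = traj.topology
        ids = [int(m) for m in topo.lipid_molecule_ids(MoleculeType.DLPC)]
        prof = chain_order_parameter(traj.frames[-3:], topo, ids, "DLPC")
        assert np.all(prof.s >= -0.5 - 1e-9) and np.all(prof.s <= 1.0 + 1e-9)

    def test_region_tilts_recovered(self, small_raft):
        # ordered disk at 10 deg, disordered background at 30 deg
        topo, frame, gt = small_raft
        for mtype, region in ((MoleculeType.DPPC, "Lo"), (MoleculeType.DLPC, "Ld")):
            ids = [int(m) for m in topo.lipid_molecule_ids(mtype)
                   if gt.pc_domains.get(int(m)) == region]
            prof = chain_order_parameter([frame], topo, ids, mtype)
            theta = math.radians(gt.tilt_by_region[region])
            want = 0.5 * (3.0 * math.cos(theta) ** 2 - 1.0)
            assert prof.s.mean() == pytest.approx(want, abs=0.05)


class TestGroupComparisons:
    def test_identical_groups_zero_delta(self):
        topo, frames, _ = generate_tilted_chains(25.0, n_lipids=9)
        ids = [int(m) for m in topo.lipid_molecule_ids()]
        p = chain_order_parameter(frames, topo, ids, "DPPC", group="annular")
        q = chain_order_parameter(frames, topo, ids, "DPPC", group="nAL")
        out = annular_vs_nonannular(p, q)
        assert out["delta_S"].abs().max() == 0.0

    def test_tilted_annular_lower_order(self):
        # annular chains tilted 30 deg more than far field -> delta S < 0
        t1, f1, s1 = generate_tilted_chains(40.0, n_lipids=9, seed=1)
        t2, f2, s2 = generate_tilted_chains(10.0, n_lipids=9, seed=2)
        p = chain_order_parameter(f1, t1, [int(m) for m in t1.lipid_molecule_ids()],
                                  "DPPC", group="annular")
        q = chain_order_parameter(f2, t2, [int(m) for m in t2.lipid_molecule_ids()],
                                  "DPPC", group="nAL")
        out = annular_vs_nonannular(p, q)
        assert (out["delta_S"] < 0).all()
        assert out["delta_S"].iloc[0] == pytest.approx(s1 - s2, abs=1e-9)

    def test_replicate_aggregation(self):
        profs = []
        for seed in (1, 2, 3):
            t, f, _ = generate_tilted_chains(30.0, n_lipids=9, seed=seed,
                                             jitter_sigma=0.01)
            profs.append(
                chain_order_parameter(f, t, [int(m) for m in t.lipid_molecule_ids()], "DPPC")
            )
        agg = aggregate_order_profiles(profs)
        assert agg.s == pytest.approx(np.mean([p.s for p in profs], axis=0))
        assert np.all(agg.sem >= 0)

    def test_absent_group_absent_not_zero(self):
        out = grouped_metric_comparison({"annular": {1: 4.0, 2: 4.2}, "nAL": {}})
        assert list(out["group"]) == ["annular"]
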