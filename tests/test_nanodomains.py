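"""Nanodomain classification, cluster detection, composition conservation."""
import numpy as np

from raftbind.config import MoleculeType
from raftbind.core import Atom, Frame, Topology, Trajectory
from raftbind.geometry import pairwise_distances
from raftbind.nanodomains import (
    BOTTOM,
    TOP,
    assign_chol_domains,
    assign_leaflets,
    classify_pc_domains,
    cluster_domain_context,
    domain_composition_timeseries,
    find_clusters,
)


def _mini_system(molecules):
    """molecules: list of (molecule_type, [(name, xyz), ...])."""
    atoms, pos = [], []
    for mid, (mtype, beads) in enumerate(molecules, start=1):
        for name, xyz in beads:
            atoms.append(
                Atom(len(atoms) + 1, name, 1, mtype.value, mid, mtype)
            )
            pos.append(xyz)
    refs = {
        t: ("PO4", (("C1A",),)) for t in (MoleculeType.DPPC, MoleculeType.DLPC, MoleculeType.POPS)
    }
    refs[MoleculeType.CHOL] = ("ROH", (("R1",),))
    topo = Topology(atoms, lipid_reference_atoms=refs)
    return topo, Frame(np.array(pos, dtype=float), np.array([20.0, 20.0, 20.0]))


def _pc(mtype, x, y, z=12.0):
    return (mtype, [("PO4", [x, y, z]), ("C1A", [x, y, z - 0.3])])


class TestLeaflets:
    def test_construction_recovered(self, small_raft):
        topo, frame, gt = small_raft
        leaf = assign_leaflets(frame, topo)
        assert leaf.labels == gt.leaflets

    def test_midplane_relative(self, small_raft):
        topo, frame, gt = small_raft
        shifted = Frame(frame.positions + [0.0, 0.0, 3.0], frame.box + 6.0, frame.time)
        leaf = assign_leaflets(shifted, topo)
        assert leaf.labels == gt.leaflets

    def test_monolayer_all_top(self):
        topo, frame = _mini_system([_pc(MoleculeType.DPPC, 1, 1), _pc(MoleculeType.DPPC, 2, 1)])
        leaf = assign_leaflets(frame, topo)
        assert set(leaf.labels.values()) == {TOP}


class TestClassifyPcDomains:
    def test_close_pair_both_lod(self):
        topo, frame = _mini_system(
            [_pc(MoleculeType.DPPC, 1.0, 1.0), _pc(MoleculeType.DLPC, 1.4, 1.0)]
        )
        lab = classify_pc_domains(frame, topo)
        assert set(lab.pc_labels.values()) == {"Lod"}

    def test_isolated_lipids_pure(self):
        topo, frame = _mini_system(
            [_pc(MoleculeType.DPPC, 1.0, 1.0), _pc(MoleculeType.DLPC, 5.0, 5.0)]
        )
        lab = classify_pc_domains(frame, topo)
        assert sorted(lab.pc_labels.values()) == ["Ld", "Lo"]

    def test_matches_brute_force_on_jittered_frames(self, lod_raft):
        topo, frame, gt = lod_raft
        leaf = assign_leaflets(frame, topo)
        lab = classify_pc_domains(frame, topo, leaf)
        # exhaustive oracle: per leaflet, all DPPC x DLPC atom distances
        for leaflet in (TOP, BOTTOM):
            dp = [m for m in topo.lipid_molecule_ids(MoleculeType.DPPC) if leaf.labels[int(m)] == leaflet]
            dl = [m for m in topo.lipid_molecule_ids(MoleculeType.DLPC) if leaf.labels[int(m)] == leaflet]
            dl_atoms = np.concatenate([topo.molecule_atom_indices(int(m)) for m in dl])
            for m in dp:
                d = pairwise_distances(
                    frame.positions[topo.molecule_atom_indices(int(m))],
                    frame.positions[dl_atoms],
                    frame.box,
                ).min()
                want = "Lod" if d <= 0.5 else "Lo"
                assert lab.pc_labels[int(m)] == want

    def test_ground_truth_recovery(self, lod_raft):
        topo, frame, gt = lod_raft
        lab = classify_pc_domains(frame, topo)
        assert lab.pc_labels == gt.pc_domains

    def test_threshold_monotonicity(self, lod_raft):
        topo, frame, _ = lod_raft
        lod_small = {
            m for m, v in classify_pc_domains(frame, topo, threshold=0.5).pc_labels.items()
            if v == "Lod"
        }
        lod_big = {
            m for m, v in classify_pc_domains(frame, topo, threshold=0.9).pc_labels.items()
            if v == "Lod"
        }
        assert lod_small <= lod_big


class TestCholDomains:
    def test_nearest_pc_wins(self):
        topo, frame = _mini_system(
            [
                _pc(MoleculeType.DPPC, 1.0, 1.0),            # Lo (isolated from DLPC? no:)
                _pc(MoleculeType.DLPC, 1.45, 1.0),           # within 0.45 -> both Lod
                (MoleculeType.CHOL, [("ROH", [1.15, 1.0, 12.0]), ("R1", [1.15, 1.0, 11.7])]),
            ]
        )
        lab = classify_pc_domains(frame, topo)
        lab = assign_chol_domains(frame, topo, lab)
        assert lab.chol_labels[3] == "Lod"

    def test_out_of_range_unassigned(self):
        topo, frame = _mini_system(
            [
                _pc(MoleculeType.DPPC, 1.0, 1.0),
                (MoleculeType.CHOL, [("ROH", [5.0, 5.0, 12.0]), ("R1", [5.0, 5.0, 11.7])]),
            ]
        )
        lab = classify_pc_domains(frame, topo)
        lab = assign_chol_domains(frame, topo, lab)
        assert lab.chol_labels[2] == "UNASSIGNED"

    def test_ground_truth_recovery(self, small_raft):
        topo, frame, gt = small_raft
        lab = classify_pc_domains(frame, topo)
        lab = assign_chol_domains(frame, topo, lab)
        assert {m: lab.chol_labels[m] for m in gt.chol_domains} == gt.chol_domains


class TestClusters:
    def test_single_link(self):
        topo, frame = _mini_system(
            [_pc(MoleculeType.POPS, 1.0, 1.0), _pc(MoleculeType.POPS, 1.4, 1.0)]
        )
        cs = find_clusters(frame, topo, MoleculeType.POPS)
        assert cs.sizes == [2]

    def test_transitivity(self):
        topo, frame = _mini_system(
            [
                _pc(MoleculeType.POPS, 1.0, 1.0),
                _pc(MoleculeType.POPS, 1.4, 1.0),
                _pc(MoleculeType.POPS, 1.8, 1.0),
            ]
        )
        cs = find_clusters(frame, topo, MoleculeType.POPS)
        assert cs.sizes == [3]

    def test_scattered_singletons(self):
        mols = [_pc(MoleculeType.POPS, 2.0 * i + 1, 2.0 * (i % 3) + 1) for i in range(10)]
        topo, frame = _mini_system(mols)
        cs = find_clusters(frame, topo, MoleculeType.POPS, linkage_cutoff=0.5)
        assert cs.sizes == [1] * 10

    def test_refinement_under_cutoff(self, small_raft):
        topo, frame, _ = small_raft
        small = find_clusters(frame, topo, MoleculeType.GM1, 0.3)
        big = find_clusters(frame, topo, MoleculeType.GM1, 0.6)
        assert len(small) >= len(big)
        for c in small.clusters:  # refinement: each small cluster inside one big
            assert any(c <= C for C in big.clusters)

    def test_ground_truth_recovery(self, small_raft):
        topo, frame, gt = small_raft
        cs = find_clusters(frame, topo, MoleculeType.GM1, 0.5)
        got = sorted(sorted(c) for c in cs.clusters)
        want = sorted(sorted(c) for c in gt.clusters["GM1"])
        assert got == want

    def test_domain_context(self, small_raft):
        topo, frame, gt = small_raft
        lab = classify_pc_domains(frame, topo)
        cs = find_clusters(frame, topo, MoleculeType.GM1, 0.5)
        assert cluster_domain_context(frame, topo, cs, lab) == gt.cluster_context["GM1"]


class TestCompositionTimeseries:
    def test_conservation_and_ground_truth(self, small_raft):
        topo, frame, gt = small_raft
        traj = Trajectory(topo, [Frame(frame.positions, frame.box, float(t)) for t in range(3)])
        df, means = domain_composition_timeseries(traj)
        n_dppc = len(topo.lipid_molecule_ids(MoleculeType.DPPC))
        n_dlpc = len(topo.lipid_molecule_ids(MoleculeType.DLPC))
        n_chol = len(topo.lipid_molecule_ids(MoleculeType.CHOL))
        for _, row in df.iterrows():
            assert row["Lo_DPPC"] + row["Lod_DPPC"] == n_dppc
            assert row["Ld_DLPC"] + row["Lod_DLPC"] == n_dlpc
            assert (
                row["Lo_CHOL"] + row["Ld_CHOL"] + row["Lod_CHOL"] + row["UNASSIGNED_CHOL"]
                == n_chol
            )
        # static frames: zero variance
        assert df.drop(columns="time").std().max() == 0.0
        # separated construction: no boundary ring -> no Lod
        assert means["Lod_DPPC"] == 0 and means["Lod_DLPC"] == 0
        assert means["n_clusters_GM1"] == len(gt.clusters["GM1"])
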