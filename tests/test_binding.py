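"""Binding kinetics, residue spectra, hydropathy and charge descriptors."""
import numpy as np
import pytest

from raftbind.binding import (
    MindistSeries,
    aggregate_spectra,
    bound_leaflet,
    detect_binding_time,
    hydropathy_profile,
    mindist_timeseries,
    moving_average,
    residue_mindist_spectrum,
    sequence_charge,
    smooth_spectrum,
)
from raftbind.config import HIAPP_SEQUENCE, MoleculeType
from raftbind.errors import RaftbindError
from raftbind.geometry import AtomSelection
from raftbind.nanodomains import assign_leaflets

from conftest import brute_distance_matrix


def _series(times, d, **kw):
    return MindistSeries("DPPC", np.asarray(times, float), np.asarray(d, float),
                         np.zeros(len(times)), **kw)


class TestDetectBindingTime:
    def test_ideal_step(self):
        t = np.arange(0.0, 300.0, 1.0)
        d = np.where(t < 100.0, 5.0, 0.5)
        ev = detect_binding_time(_series(t, d), 0.7, 50.0, 0.95)
        assert ev.t_bind == 100.0

    def test_never_bound(self):
        t = np.arange(0.0, 200.0, 1.0)
        ev = detect_binding_time(_series(t, np.full_like(t, 3.0)), 0.7, 50.0, 0.95)
        assert ev.t_bind is None

    def test_transient_dip_rejected(self):
        t = np.arange(0.0, 400.0, 1.0)
        d = np.full_like(t, 5.0)
        d[(t >= 50) & (t < 55)] = 0.5          # 5 ns touch
        d[t >= 200] = 0.5                      # sustained binding
        ev = detect_binding_time(_series(t, d), 0.7, 50.0, 0.95)
        assert ev.t_bind == 200.0
        # exhaustive scan oracle: first index whose window occupancy passes
        # and with no long excursion afterwards
        def ok(i):
            win = (t >= t[i]) & (t <= t[i] + 50.0)
            if (d[win] <= 0.7).mean() < 0.95:
                return False
            after = d[i:] > 0.7
            run = best = 0
            for x in after:
                run = run + 1 if x else 0
                best = max(best, run)
            return best * 1.0 <= (1 - 0.95) * 50.0
        first = next(t[i] for i in range(len(t)) if d[i] <= 0.7 and ok(i))
        assert ev.t_bind == first

    def test_prepend_invariance(self):
        t = np.arange(0.0, 300.0, 1.0)
        d = np.where(t < 100.0, 5.0, 0.5)
        base = detect_binding_time(_series(t, d), 0.7, 50.0, 0.95).t_bind
        t2 = np.arange(0.0, 350.0, 1.0)
        d2 = np.concatenate([np.full(50, 4.0), d])
        shifted = detect_binding_time(_series(t2, d2), 0.7, 50.0, 0.95).t_bind
        assert shifted == base + 50.0

    def test_dwell_longer_than_span_rejected(self):
        t = np.arange(0.0, 10.0, 1.0)
        with pytest.raises(RaftbindError):
            detect_binding_time(_series(t, np.ones_like(t)), 0.7, 50.0, 0.95)


class TestMindistTimeseries:
    def test_matches_brute_force(self, binding_traj):
        traj, _ = binding_traj
        prot = AtomSelection("p", traj.topology.protein_indices())
        series = mindist_timeseries(traj, prot, MoleculeType.DPPC)
        part = traj.topology.type_indices(MoleculeType.DPPC)
        for k in range(0, traj.n_frames, 13):
            frame = traj.frames[k]
            dmat = brute_distance_matrix(
                frame.positions[prot.indices], frame.positions[part], frame.box
            )
            assert series.d_min[k] == pytest.approx(dmat.min(), abs=1e-5)
            assert series.contacts[k] == int((dmat < 2.0).sum())

    def test_binding_time_recovered(self, binding_traj):
        traj, gt = binding_traj
        prot = AtomSelection("p", traj.topology.protein_indices())
        series = mindist_timeseries(traj, prot, MoleculeType.DPPC)
        ev = detect_binding_time(series, 0.7, 20.0, 0.95)
        assert ev.t_bind == pytest.approx(gt.binding_time, abs=1.0)

    def test_bound_leaflet_is_top(self, binding_traj):
        traj, gt = binding_traj
        prot = AtomSelection("p", traj.topology.protein_indices())
        series = mindist_timeseries(traj, prot, MoleculeType.DPPC)
        ev = detect_binding_time(series, 0.7, 20.0, 0.95)
        leaf = assign_leaflets(traj.frames[-1], traj.topology)
        ev = bound_leaflet(traj, series, ev, leaf)
        assert ev.bound_leaflet == gt.binding_leaflet == "TOP"


class TestResidueSpectrum:
    def test_anchor_residues_are_smallest(self, binding_traj):
        traj, gt = binding_traj
        spec = residue_mindist_spectrum(
            traj, "last 20 ns", [MoleculeType.DPPC, MoleculeType.WATER]
        )
        lipid = spec.chain_averaged("DPPC")
        assert sorted(np.argsort(lipid)[:2] + 1) == sorted(gt.anchor_residues)

    def test_water_peaks_at_lipid_dips(self, binding_traj):
        traj, gt = binding_traj
        spec = residue_mindist_spectrum(
            traj, "last 20 ns", [MoleculeType.DPPC, MoleculeType.WATER]
        )
        water = spec.chain_averaged("WATER")
        anchors = [r - 1 for r in gt.anchor_residues]
        others = np.delete(np.arange(len(water)), anchors)
        assert water[anchors].min() > water[others].mean()

    def test_nterm_contact_mode(self, gm_binding_traj):
        traj, gt = gm_binding_traj
        spec = residue_mindist_spectrum(traj, "last 10 ns", [MoleculeType.GM1])
        gm1 = spec.chain_averaged("GM1")
        nterm = gm1[:12]
        assert nterm.max() < gm1[12:].min()          # minima in residues 1-12
        assert int(np.argmax(gm1)) + 1 == 26          # peak at residue 26

    def test_chain_and_replicate_averaging(self):
        # two replicates of two chains, constructed per-chain means
        class S:
            def __init__(self, arrs):
                self.per_chain = {"DPPC": np.asarray(arrs, float)}

            def chain_averaged(self, p):
                return self.per_chain[p].mean(axis=0)

        r1 = S([[0.4, 1.0], [0.6, 1.0]])   # chain-avg (0.5, 1.0)
        r2 = S([[0.7, 2.0], [0.7, 2.0]])   # chain-avg (0.7, 2.0)
        mean, sem = aggregate_spectra([r1, r2], "DPPC")
        assert mean == pytest.approx([0.6, 1.5])
        # sd([0.5,0.7])/sqrt(2) = 0.1; sd([1,2])/sqrt(2) = 0.5
        assert sem == pytest.approx([0.1, 0.5])

    def test_matches_per_frame_brute_force(self, binding_traj):
        traj, _ = binding_traj
        from raftbind.core import window_select

        win = window_select(traj, (50.0, 54.0))
        spec = residue_mindist_spectrum(win, None, [MoleculeType.DPPC])
        topo = traj.topology
        part = topo.type_indices(MoleculeType.DPPC)
        res_atoms = topo.residue_atom_indices("A")
        want = np.zeros(len(res_atoms))
        for frame in win.frames:
            for r, atoms in enumerate(res_atoms):
                want[r] += brute_distance_matrix(
                    frame.positions[atoms], frame.positions[part], frame.box
                ).min()
        want /= win.n_frames
        assert spec.chain_averaged("DPPC") == pytest.approx(want, abs=1e-5)


class TestSequenceDescriptors:
    def test_hiapp_charge(self):
        rec = sequence_charge(HIAPP_SEQUENCE)
        assert rec.net_charge == 2
        assert rec.basic_positions == [1, 11]

    @pytest.mark.parametrize("seq,charge", [("AAAA", 0), ("KRKR", 4)])
    def test_simple_charges(self, seq, charge):
        assert sequence_charge(seq).net_charge == charge

    def test_hiapp_hydropathy_raw_peaks(self):
        prof = hydropathy_profile(HIAPP_SEQUENCE, window=5)
        assert prof.raw[15] == 3.8   # L16, leucine scale value
        assert prof.raw[25] == 4.5   # I26, isoleucine scale value
        assert prof.raw[15] > 2.0 and prof.raw[25] > 2.0

    def test_constant_sequence_flat(self):
        prof = hydropathy_profile("AAAAAAAAA")
        assert np.allclose(prof.raw, 1.8) and np.allclose(prof.smoothed, 1.8)

    def test_window_one_identity(self):
        prof = hydropathy_profile(HIAPP_SEQUENCE, window=1)
        assert np.array_equal(prof.raw, prof.smoothed)

    def test_unknown_letter_rejected(self):
        with pytest.raises(RaftbindError):
            hydropathy_profile("AXZ")

    def test_moving_average_truncated_edges(self):
        out = moving_average(np.array([1.0, 2.0, 3.0, 4.0]), 3)
        assert out == pytest.approx([1.5, 2.0, 3.0, 3.5])
        assert smooth_spectrum(np.array([0.0, 3.0, 0.0])) == pytest.approx([1.5, 1.0, 1.5])
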