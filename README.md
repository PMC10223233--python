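# raftbind

Trajectory analysis of amyloid-oligomer binding to phase-separated
lipid-raft membranes.

Disordered amyloid peptides such as human amylin (hIAPP, the 37-residue
peptide `KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY`) adsorb onto plasma-membrane
surfaces whose lipids are laterally organized into coexisting
liquid-ordered (Lo, saturated-lipid + cholesterol rich), liquid-disordered
(Ld, unsaturated-lipid rich) and mixed boundary (Lod) nanodomains, with
optional one-leaflet clusters of anionic POPS or ganglioside GM1.  Which
nanodomain the oligomer binds, which residues anchor it, and how the
binding perturbs the surrounding lipids are questions answered from
molecular-dynamics trajectories — and that analysis layer is what this
package implements, for people who have such trajectories (coarse-grained
or all-atom) and want reproducible, tested numbers rather than one-off
scripts:

- **Nanodomain classification** — a DPPC is Lod iff any of its atoms lies
  within 0.5 nm of a same-leaflet DLPC atom (else Lo), and symmetrically
  for DLPC; cholesterol inherits the domain of its nearest PC within the
  same threshold; POPS/GM1 clusters are single-linkage connected
  components.
- **Annular lipid shells** — each lipid is binned by its minimum any-atom
  distance *d* to the bound protein into shells 0–0.5, 0.5–1, 1–2, 2–3 nm
  (half-open, inner < *d* ≤ outer), plus the 0–1.2 nm shell whose lipid
  count normalizes protein–lipid nonbonded energies Ê(t) = E(t)/N₁.₂(t);
  compositions are reported per type with replicate mean ± SEM.
- **Binding kinetics** — per-partner minimum-distance (mindist) and
  contact-count (pairs within 2 nm) time series; the binding time is the
  earliest t from which the mindist stays ≤ d_bound (0.7 nm) for a dwell
  period at ≥ 95 % occupancy, a robust formalization of the abrupt
  solution→bound transition.
- **Residue-resolved spectra** — time-, chain- and replicate-averaged
  minimum distance per residue and partner species, with Kyte–Doolittle
  hydropathy and net-charge overlays for interpretation.
- **Membrane disruption** — per-lipid bilayer thickness (opposing-leaflet
  headgroup plane within a 2.5 nm lateral radius), area per lipid (periodic
  planar Voronoi tessellation; cell areas sum exactly to the box area) and
  the acyl-chain order parameter S(k) = (3⟨cos²θₖ⟩ − 1)/2 with θₖ the angle
  between the carbon k−1 → k+1 axis and the bilayer normal, compared
  annular vs non-annular.
- **Folding kinetics** — 8-state secondary-structure timelines (DSSP codes,
  consumed from files) regrouped into beta (E,B), helix (H,G,I), turn (T)
  and random (S,C), with per-frame fractions and replicate-averaged
  occurrence fractions.
- **Synthetic ground truth** — a first-class generator that builds planar
  raft bilayers with prescribed domains, clusters, chain tilts, binding
  times and anchor residues, so every analysis stage can be validated
  against labels that are true by construction.

## Worked example

```python
import numpy as np
from raftbind.binding import (detect_binding_time, hydropathy_profile,
                              mindist_timeseries, residue_mindist_spectrum,
                              sequence_charge)
from raftbind.config import HIAPP_SEQUENCE
from raftbind.geometry import AtomSelection
from raftbind.synthetic import SyntheticSpec, generate_binding_trajectory

rec = sequence_charge(HIAPP_SEQUENCE)
prof = hydropathy_profile(HIAPP_SEQUENCE)
print("net charge:", rec.net_charge, "basic residues:", rec.basic_positions)
print("raw hydropathy at residues 16, 26:", prof.raw[15], prof.raw[25])

spec = SyntheticSpec(n_frames=60, binding_time=20.0)   # bind at 20 ns
traj, gt = generate_binding_trajectory(spec, seed=1)
protein = AtomSelection("protein", traj.topology.protein_indices())
series = mindist_timeseries(traj, protein, "DPPC")
event = detect_binding_time(series, d_bound=0.7, dwell=20.0, occupancy=0.95)
print("detected binding time:", event.t_bind, "ns (true:", gt.binding_time, "ns)")

spectrum = residue_mindist_spectrum(traj, "last 20 ns", ["DPPC"])
dips = np.argsort(spectrum.chain_averaged("DPPC"))[:2] + 1
print("two closest-contact residues:", sorted(int(r) for r in dips))
```

prints

```
net charge: 2 basic residues: [1, 11]
raw hydropathy at residues 16, 26: 3.8 4.5
detected binding time: 20.0 ns (true: 20.0 ns)
two closest-contact residues: [16, 26]
```

i.e. the peptide carries +2e at K1/R11, its two hydrophobic peaks sit at
L16 and I26, the change-point detector recovers the constructed 20 ns
binding event exactly, and the residue spectrum's two deepest lipid dips
are the anchor residues the generator buried below the headgroup plane.

A command-line front end runs the same stages end to end and writes TSV
tables plus a provenance manifest recording every threshold:

```sh
raftbind run-all --seed 1 --out demo_out     # synthetic demo system
raftbind expand-grid                          # the 3 sizes x 3 rafts x 3 replicates grid
```

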