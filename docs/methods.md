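# Methods

This note records the models, conventions and numerical choices behind
raftbind's analysis stages, what the synthetic generator does and does not
emulate, and the known limitations.

## Data model and units

All lengths are nanometres internally; PDB ångströms are converted at the
I/O boundary.  Times are nanoseconds.  Boxes are orthorhombic edge lengths
only — triclinic inputs raise an explicit unsupported-feature error,
because the planar raft membranes this package targets live in near-cuboid
boxes and supporting general cells would complicate every minimum-image
computation for no use case.  Coarse-grained "effective time" (the ~4×
speed-up of coarse-grained diffusion relative to real time) is available
as a reporting transform (`Trajectory.effective_times`) but is never
applied to stored time stamps.

Molecule types (DPPC, DLPC, CHOL, POPS, GM1, protein, water, ion) are
inferred from residue names through a configurable map; in lenient mode
unmapped names become ions, in strict mode they raise.  Protein chains are
detected as contiguous runs of amino-acid residues whose numbering
restarts; each chain carries a one-letter sequence checked against its
residue count.

Replicate statistics everywhere use the arithmetic mean and the sample
(n−1) standard deviation divided by √n.  With three replicates the
unbiased estimator matters; a single replicate yields SEM 0 and is flagged.
Averaging windows are either explicit intervals or trailing spans
(`"last 5 us"`, `"last 50 ns"`), endpoints inclusive.

## Periodic geometry

Minimum-image distances, neighbor searches, group minimum distances and
contact counts are built on MDAnalysis' distance kernels
(`distance_array`, `capped_distance`); the test suite cross-checks them
against an independent explicit 27-image enumeration.  Two boundary
conventions are fixed for determinism: contact counting uses a strict
`<` cutoff, while threshold membership (domain proximity, shell binning,
cluster linkage) uses `≤`.  The distinction is measure-zero for real data
but keeps constructed fixtures deterministic.  Neighbor queries refuse
cutoffs above half the smallest box edge (minimum image becomes ambiguous)
and direct the caller to the brute-force route.  The kernels compute in
single precision internally; all tolerances in the tests respect the
~1e-5 nm accuracy this implies.

Contacts count atom *pairs*, not distinct atoms, matching the usual
interpretation of contact-number curves as interaction extent.

## Nanodomain classification

A DPPC is Lod iff any of its atoms lies within the proximity threshold
(default 0.5 nm) of any atom of a *same-leaflet* DLPC, else Lo; DLPC
symmetrically Lod/Ld.  The same-leaflet restriction is deliberate:
atom-atom contacts across the bilayer midplane would spuriously merge
domains that are resolved per leaflet.  Leaflets are assigned by headgroup
reference z against the midplane (mean reference z); if the reference
spread is below 1.5 nm the input is treated as a monolayer (all TOP, with
a warning) because a mean-based midplane would otherwise split a single
leaflet in half.

Cholesterol is labeled by the domain of its *nearest* PC atom within the
threshold, UNASSIGNED otherwise.  The any-atom-within-0.5-nm relation is
multi-valued where domains meet; the nearest-atom rule turns it into the
partition that composition tables need.

POPS/GM1 clusters are single-linkage connected components: lipids linked
iff any inter-lipid atom pair is within the linkage cutoff.  The cutoff
defaults to 0.5 nm — the same scale as the domain rule — and is exposed as
configuration, since no single value is canonical.  A cluster's domain
context is the majority Lo/Ld/Lod label of PC lipids within 0.5 nm of its
members, which reproduces the "GM1 clusters inside the ordered domain /
PS clusters at the boundary" bookkeeping.

Raising the proximity threshold can only grow the Lod set, and cluster
sets at a smaller cutoff refine those at a larger one; both monotonicity
properties are asserted in the tests.

## Annular shells and energies

A lipid's shell is determined by its minimum any-atom distance d to the
protein: bins (0, 0.5], (0.5, 1], (1, 2], (2, 3] nm, NON_ANNULAR beyond.
Half-open binning makes the printed single thresholds (0.5, 1.2) behave as
inclusive outer bounds.  Water and ions are never shell members.
Percentages are per-frame type fractions of the bin total; frames with an
empty bin contribute no percentage sample and are excluded with a warning
(the smallest shell is frequently empty before binding).  Aggregation
order is window mean first, then replicate mean ± SEM.

Nonbonded protein–lipid energies are *consumed* from tables (time,
partner_type, E_LJ, E_Coulomb in kJ/mol); force-field evaluation is out of
scope.  The normalized energy divides each sample by the lipid count of
the (0, 1.2] nm shell at the same time stamp; time axes must match exactly
(no interpolation), and samples with an empty shell are dropped with a
warning rather than producing infinities.

## Membrane structure

The bilayer normal is the fixed z-axis; these are planar membranes and no
local-normal estimation is attempted.  Per-lipid thickness is
|z_ref − ⟨z_ref of opposing-leaflet lipids within a 2.5 nm lateral
(minimum-image xy) radius⟩|; the radius is configuration because no single
neighborhood rule is canonical, and lipids without an opposing neighbor
are skipped with a warning rather than silently extrapolated.

Area per lipid tessellates the leaflet's headgroup reference points in the
xy-plane under periodic boundaries: points are tiled into 3×3 images,
scipy's Voronoi diagram is computed, and each central-copy cell's polygon
area is the lipid's APL.  The construction guarantees ΣAPL = Lx·Ly per
leaflet to floating-point accuracy, which the tests assert at 1e-6
relative tolerance.

The chain order parameter at carbon k uses the molecular axis from carbon
k−1 to k+1: S(k) = (3⟨cos²θ⟩ − 1)/2 averaged over window frames, selected
lipids and both acyl chains, reported for interior carbons 2..n−1.  The
sign convention is the P2 form (1 aligned, 0 isotropic, −0.5 in-plane),
not −S_CD; output headers record this.  For coarse-grained lipids the same
three-point rule applies to consecutive chain beads and "carbon" means
bead index.  Annular-vs-non-annular comparisons report ΔS with SEMs added
in quadrature; absent groups are reported as absent, never as zero.

## Binding kinetics and spectra

The binding time formalizes an "abrupt transition to a small, stable
mindist" as: the earliest sample time t such that within [t, t + dwell]
the fraction of samples with d_min ≤ d_bound is at least the occupancy,
and after t the series never exceeds d_bound for a contiguous run longer
than (1 − occupancy)·dwell.  Defaults: d_bound 0.7 nm (bead-contact
scale), dwell 500 ns for coarse-grained runs / 20 ns for all-atom runs,
occupancy 0.95.  The trailing-excursion clause rejects transient touches
that precede the final adsorption.  The bound leaflet is the leaflet of
the lipid achieving d_min at the detected time.

Residue spectra average the per-frame minimum distance between residue-r
atoms and partner atoms over the window, pooling residue r across chains.
Aggregation order: chains are averaged within a replicate first, then the
SEM is taken across replicates — so the error bar reflects replicate
scatter, not chain-to-chain variation within one system.  A 3-point
moving average is available for peak/dip reporting on spectra; hydropathy
profiles use the Kyte–Doolittle scale with a centered 5-point moving
average whose edges use the truncated window.  Note that with the
standard scale the centered smoothed profile peaks on the shoulders of
L16/I26 while the *raw* indices at those residues exceed 2.0; both are
reported, and the raw values are the headline quantities.  Net charge
counts K and R only (termini and histidine neutral) — the convention for
this peptide at neutral pH.

Whether hydrogens should enter all-atom mindist computations is not
standardized; all atoms are included by default and selections can
exclude them.

## Secondary structure

The DSSP assignment algorithm is *not* implemented; 8-state code matrices
(residues × frames) are read from TSV (tab-separated cells) or raw
character rows, with `~`/`-` normalized to coil.  Regrouping: E,B → beta;
H,G,I → helix; T → turn; S,C → random.  Occurrence fractions count
residue-frames (a residue in a state for k frames contributes k), the
natural reading of "number of occurrences" for timeline data; the
alternative residues-ever-in-state reading is not used.  Distinguishing
inter- from intra-chain beta sheets requires hydrogen-bond partners that
code matrices do not carry, so it is out of scope.

## Synthetic generator

The generator produces labeled systems, not physics: dynamics are
scripted positions plus Gaussian jitter, with no forces.  Its purpose is
ground truth that the analysis operations must recover exactly, so the
geometry is margin-engineered: PC regions of different type are separated
by empty rings (default 2.0 nm) several times the 0.5 nm threshold even
after chain tilt excursions and jitter; mixed-ring DPPC/DLPC pairs sit
0.4 nm apart (always within threshold); cluster members sit 0.45 nm apart
(always linked) while clusters are ≥ 3 nm from each other.  One explicit
PC lipid placed 0.4 nm from each cluster pins its domain context
deterministically (this lipid is additional to the requested counts).

Defaults mirror the study conditions at reduced lateral scale: the
ordered-raft composition 828:540:576 DPPC:DLPC:CHOL scaled by 1/12 to
69:45:48, a 22×22 nm membrane scaled to 12×12 nm (14 nm when a mixed ring
or clusters need more lattice area), 4 nm headgroup-plane separation,
protein start ≥ 5 nm above the surface, replicate x-offsets 0/+2/−2 nm
applied at t = 0 with an otherwise identical lateral random walk, binding
at a prescribed time, anchor residues 16 and 26 buried ~0.3 nm below the
nearest headgroup in the anchored mode, and residues 1–12 in contact
(residue 26 lifted) in the N-terminal/ganglioside mode.  Water is a
sparse placeholder grid above the top leaflet — enough to make
water-mindist anticorrelate with lipid-mindist at buried residues, not a
solvent model.  Chain tilts are fixed cone angles per region (10° ordered
disk, 30° background, 20° mixed ring) with deterministic azimuths, giving
closed-form order parameters.  Frame spacing defaults to 1 ns, a free
choice since no saving interval is canonical.  Identical (spec, seed)
yield byte-identical outputs.

What passing on this generator does **not** show: recovery on thermally
disordered boundaries (real Lod margins are fuzzy, not margin-engineered),
curved or undulating membranes, lipid flip-flop, realistic water, or the
multi-microsecond kinetics behind published binding times — those
headline numbers come from large simulations and are out of desk-scale
reach by design; the acceptance layer therefore checks property recovery
on ground truth rather than reproducing simulation-scale values.

## Problem sizes

Test and acceptance systems use membranes of ~120–170 lipids (~1,400–2,000
beads), trajectories of 25–60 frames, 50 noisy binding replays, and 10⁴
frames × 20 residues for Markov secondary-structure recovery.  These sizes
were chosen as the smallest at which every recovery check is
non-degenerate (multiple lipids per shell, clusters of double-digit size,
3σ stationary statistics).

## Known limitations

- Orthorhombic boxes and a fixed z normal only; no curvature fields.
- The CHOL nearest-PC rule and the majority-vote cluster context are
  package conventions where the underlying relations are multi-valued.
- Energy tables must share the exact time grid of the shell counts; no
  interpolation is attempted.
- GRO round-trips are exact only to the format's printed precision
  (3 decimals in nm); multi-model PDB likewise to 3 decimals in Å.
- The binding-time criterion is a change-point convention; pathological
  series that hover at d_bound can shift the detected time by up to the
  dwell length.
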