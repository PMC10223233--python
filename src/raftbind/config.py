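"""Default parameters and residue-name vocabulary.

Every threshold used by the analysis stages lives here as a named default so
that no stage hard-codes a number: the domain proximity threshold (0.5 nm),
the contact cutoff (2 nm), the annular-shell scheme (0.5 / 0.5-1 / 1-2 /
2-3 nm plus the 1.2 nm energy shell), the binding-detection criterion and
the averaging windows (last 5 us of a coarse-grained run, last 50 ns of an
all-atom run).
"""
from __future__ import annotations

from enum import Enum


class MoleculeType(str, Enum):
    """Coarse molecular species vocabulary of the raft systems."""

    DPPC = "DPPC"
    DLPC = "DLPC"
    CHOL = "CHOL"
    POPS = "POPS"
    GM1 = "GM1"
    PROTEIN = "PROTEIN"
    WATER = "WATER"
    ION = "ION"


LIPID_TYPES = (
    MoleculeType.DPPC,
    MoleculeType.DLPC,
    MoleculeType.CHOL,
    MoleculeType.POPS,
    MoleculeType.GM1,
)

#: Three-letter amino-acid residue names (both AA force fields and the
#: one-bead-per-residue coarse model emit these).
AMINO_ACID_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP",
}

#: Default residue-name -> molecule-type map.  Overridable; in lenient mode
#: unmapped names fall back to ION, in strict mode they raise.
DEFAULT_RESNAME_MAP: dict[str, MoleculeType] = {
    "DPPC": MoleculeType.DPPC,
    "DLPC": MoleculeType.DLPC,
    "CHOL": MoleculeType.CHOL,
    "CHL1": MoleculeType.CHOL,
    "POPS": MoleculeType.POPS,
    "GM1": MoleculeType.GM1,
    "DPG1": MoleculeType.GM1,
    "W": MoleculeType.WATER,
    "WN": MoleculeType.WATER,
    "SOL": MoleculeType.WATER,
    "HOH": MoleculeType.WATER,
    "TIP3": MoleculeType.WATER,
    "WAT": MoleculeType.WATER,
    "NA": MoleculeType.ION,
    "CL": MoleculeType.ION,
    "NA+": MoleculeType.ION,
    "CL-": MoleculeType.ION,
    "ION": MoleculeType.ION,
}
DEFAULT_RESNAME_MAP.update({name: MoleculeType.PROTEIN for name in AMINO_ACID_RESNAMES})

#: Headgroup reference atom and ordered acyl-chain atom names per lipid type
#: (the synthetic coarse model's naming; real topologies override via
#: Topology.lipid_reference_atoms).
DEFAULT_LIPID_REFERENCE_ATOMS = {
    MoleculeType.DPPC: ("PO4", (("C1A", "C2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B"))),
    MoleculeType.DLPC: ("PO4", (("C1A", "C2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B"))),
    MoleculeType.POPS: ("PO4", (("C1A", "C2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B"))),
    MoleculeType.GM1: ("GM1H", (("C1A", "C2A", "C3A", "C4A"), ("C1B", "C2B", "C3B", "C4B"))),
    MoleculeType.CHOL: ("ROH", (("R1", "R2"),)),
}

# --- analysis thresholds (nm unless noted) ---------------------------------
DOMAIN_PROXIMITY_THRESHOLD = 0.5   #: DPPC-DLPC any-atom proximity for Lo/Ld/Lod
CLUSTER_LINKAGE_CUTOFF = 0.5       #: single-linkage cutoff for PS/GM1 clusters
CONTACT_CUTOFF = 2.0               #: protein-partner contact counting cutoff
ENERGY_SHELL = (0.0, 1.2)          #: shell normalizing nonbonded energies
STANDARD_SHELL_BINS = ((0.0, 0.5), (0.5, 1.0), (1.0, 2.0), (2.0, 3.0))

# Binding-detection criterion: earliest time from which the mindist stays
# at or below d_bound for a dwell period with the given occupancy.
BINDING_D_BOUND = 0.7              #: nm, bead-contact distance
BINDING_DWELL_CG = 500.0           #: ns
BINDING_DWELL_AA = 20.0            #: ns
BINDING_OCCUPANCY = 0.95

# Averaging windows.
WINDOW_CG = "last 5 us"
WINDOW_AA = "last 50 ns"

# Membrane-structure parameters.
THICKNESS_LATERAL_RADIUS = 2.5     #: nm, opposing-leaflet neighborhood
SPECTRUM_SMOOTHING_WINDOW = 3      #: moving-average points for mindist spectra
HYDROPATHY_WINDOW = 5              #: moving-average points for hydropathy

#: Effective-time factor for coarse-grained runs (reporting option only;
#: stored times are never rescaled).
CG_EFFECTIVE_TIME_FACTOR = 4.0

#: hIAPP (human amylin) primary sequence, one-letter codes.
HIAPP_SEQUENCE = "KCNTATCATQRLANFLVHSSNNFGAILSSTNVGSNTY"

#: Default anchor residues: the two major hydrophobic residues L16 and I26.
DEFAULT_ANCHOR_RESIDUES = (16, 26)

#: CO-raft lipid counts (DPPC, DLPC, CHOL) of the full-size system.
CO_RAFT_COUNTS = {MoleculeType.DPPC: 828, MoleculeType.DLPC: 540, MoleculeType.CHOL: 576}
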