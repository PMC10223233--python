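"""Secondary-structure timelines and surface-induced folding kinetics.

Eight-state per-residue secondary-structure codes (DSSP alphabet
H, G, I, E, B, T, S, C) are consumed from files — the hydrogen-bond
assignment itself is out of scope — then regrouped into four categories:
beta (sheet E + bridge B), helix (alpha H + 3-10 G + pi I), turn (T) and
random (bend S + coil C).  Folding kinetics are the per-frame residue
fractions of each category; occurrence fractions count residue-frames over
a whole run.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import replicate_mean_sem
from .errors import ParseError

SS_CODES = ("H", "G", "I", "E", "B", "T", "S", "C")
CATEGORIES = ("beta", "helix", "turn", "random")
CODE_TO_CATEGORY = {
    "E": "beta", "B": "beta",
    "H": "helix", "G": "helix", "I": "helix",
    "T": "turn",
    "S": "random", "C": "random",
}
_NORMALIZE = {"~": "C", "-": "C"}


@dataclass
class SSMatrix:
    """Residues x frames matrix of 8-state codes."""

    codes: np.ndarray                    # (R, F) of '<U1'
    times: np.ndarray | None = None      # ns, optional
    chain_rows: dict[str, slice] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype="<U1")
        if self.codes.ndim != 2:
            raise ParseError("secondary-structure matrix must be 2-D")
        bad = ~np.isin(self.codes, SS_CODES)
        if bad.any():
            r, f = np.argwhere(bad)[0]
            raise ParseError(
                f"invalid secondary-structure code {self.codes[r, f]!r} "
                f"at residue row {r}, frame column {f}"
            )
        if self.times is None:
            self.times = np.arange(self.codes.shape[1], dtype=np.float64)

    @property
    def n_residues(self) -> int:
        return self.codes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.codes.shape[1]


def read_ss_matrix(path, dialect: str = "TSV", times=None) -> SSMatrix:
    """Read a code matrix: one row per residue, one column per frame.

    ``TSV``: tab-separated single-character cells.  ``RAW`` (xpm-like):
    one unseparated character string per residue row.  ``~`` and ``-`` are
    normalized to coil ``C``.
    """
    dialect = dialect.upper()
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if dialect == "TSV":
                cells = line.split("\t")
            elif dialect in ("RAW", "XPM", "XPM-LIKE"):
                cells = list(line)
            else:
                raise ParseError(f"unknown secondary-structure dialect {dialect!r}")
            cells = [_NORMALIZE.get(c.strip(), c.strip()) for c in cells]
            if rows and len(cells) != len(rows[0]):
                raise ParseError(
                    f"ragged matrix: line {lineno} has {len(cells)} columns, "
                    f"expected {len(rows[0])}"
                )
            rows.append(cells)
    if not rows:
        raise ParseError(f"empty secondary-structure file {path}")
    return SSMatrix(np.array(rows), times=None if times is None else np.asarray(times))


def write_ss_matrix(matrix: SSMatrix, path, dialect: str = "TSV") -> None:
    with open(path, "w") as fh:
        for row in matrix.codes:
            if dialect.upper() == "TSV":
                fh.write("\t".join(row) + "\n")
            else:
                fh.write("".join(row) + "\n")


def regroup_ss(matrix: SSMatrix) -> np.ndarray:
    """Map the 8-state matrix onto the four folding categories."""
    lut = np.vectorize(CODE_TO_CATEGORY.__getitem__)
    return lut(matrix.codes)


def folding_kinetics(
    categories: np.ndarray, times: np.ndarray | None = None
) -> pd.DataFrame:
    """Per-frame fraction of residues in each category (columns sum to 1)."""
    categories = np.asarray(categories)
    n_res, n_frames = categories.shape
    if times is None:
        times = np.arange(n_frames, dtype=np.float64)
    data = {"time": np.asarray(times, dtype=np.float64)}
    for cat in CATEGORIES:
        data[f"f_{cat}"] = (categories == cat).sum(axis=0) / n_res
    return pd.DataFrame(data)


def occurrence_fractions(
    per_replicate: list[np.ndarray],
) -> pd.DataFrame:
    """Replicate mean +- SEM of whole-run category fractions.

    Each replicate's fraction of a category is its residue-frame cell count
    over the total number of cells in the matrix.
    """
    rows = []
    fracs = {
        cat: [float((m == cat).mean()) for m in per_replicate] for cat in CATEGORIES
    }
    for cat in CATEGORIES:
        ms = replicate_mean_sem(fracs[cat])
        rows.append({"category": cat, "fraction": ms.mean, "sem": ms.sem, "n": ms.n})
    return pd.DataFrame(rows)
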