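"""Exception hierarchy.

All package errors derive from :class:`RaftbindError` so callers can catch
one base class at pipeline level.
"""


class RaftbindError(Exception):
    """Base class for all raftbind errors."""


class ParseError(RaftbindError):
    """Malformed input file; message carries the offending line/cell."""


class LabelingError(RaftbindError):
    """A residue name could not be mapped to a molecule type in strict mode."""


class TopologyError(RaftbindError):
    """Frame/topology mismatch (atom counts, missing reference atoms)."""


class OrderingError(RaftbindError):
    """Trajectory times are not strictly increasing."""


class WindowError(RaftbindError):
    """Time-window selection produced no frames."""


class SelectionError(RaftbindError):
    """An atom selection required to be non-empty is empty."""


class QueryError(RaftbindError):
    """Neighbor-search parameters incompatible with the periodic box."""


class SchemeError(RaftbindError):
    """Invalid annular-shell scheme (overlapping or non-increasing bins)."""


class AlignmentError(RaftbindError):
    """Time axes of two series that must align do not."""


class SpecError(RaftbindError):
    """Invalid synthetic-system specification."""


class ConfigError(RaftbindError):
    """Invalid run configuration."""


class UnsupportedFeatureError(RaftbindError):
    """Input uses a feature outside the supported model (e.g. triclinic box)."""
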