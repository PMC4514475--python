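"""Exception hierarchy used across the package."""


class PorescopeError(Exception):
    """Base class for all package-specific errors."""


class TopologyError(PorescopeError):
    """A chain, residue, ring or span required by the topology cannot be resolved."""


class FormatError(PorescopeError):
    """A structure or trajectory file violates the expected format."""


class SelectionError(PorescopeError):
    """An atom selection is empty or inconsistent between structures."""


class GeometryError(PorescopeError):
    """Degenerate geometry (colinear axes, <3 fit atoms, zero-length vectors)."""


class TypingError(PorescopeError):
    """Donor/acceptor typing is unavailable for a selected residue."""


class AbsenceError(PorescopeError):
    """A required ligand or named atom is absent from the frame."""
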