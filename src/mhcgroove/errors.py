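"""Exception hierarchy shared across the package."""


class MhcGrooveError(Exception):
    """Base class for all package errors."""


class ParseError(MhcGrooveError):
    """A structure file could not be parsed."""


class FormatError(MhcGrooveError):
    """Unknown or unsupported file format."""


class SerializationError(MhcGrooveError):
    """A structure cannot be represented in the requested output format."""


class StructuralError(MhcGrooveError):
    """Inconsistent molecular topology (e.g. between trajectory frames)."""


class SelectionError(MhcGrooveError, LookupError):
    """An addressed chain/residue/atom does not exist.

    ``reason`` distinguishes ``"chain_absent"``, ``"residue_absent"`` and
    ``"atom_absent"`` so callers can tell a disordered (unmodelled) residue
    apart from a wrong atom name.
    """

    def __init__(self, message: str, reason: str = "selection"):
        super().__init__(message)
        self.reason = reason


class GeometryError(MhcGrooveError, ValueError):
    """Degenerate geometric input (collinear points, zero vectors, ...)."""


class EvaluationError(MhcGrooveError):
    """An interaction descriptor could not be evaluated; carries the
    offending atom address in ``address`` when known."""

    def __init__(self, message: str, address: tuple | None = None):
        super().__init__(message)
        self.address = address


class ValidationError(MhcGrooveError, ValueError):
    """A synthetic-data or configuration spec is internally contradictory."""
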