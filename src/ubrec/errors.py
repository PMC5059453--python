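"""Exception hierarchy shared across the package."""


class UbrecError(Exception):
    """Base class for all package errors."""


class FormatError(UbrecError):
    """A coordinate file could not be parsed; the message names the offending
    location when the underlying parser provides it."""


class EmptyStructureError(UbrecError):
    """A read or selection produced zero atoms."""


class EmptySelectionError(EmptyStructureError):
    """A selection predicate matched no atoms."""


class MissingMetadataError(UbrecError):
    """An operation needed unit-cell/symmetry metadata that is absent."""


class DegenerateGeometryError(UbrecError):
    """Input geometry is degenerate for the requested operation (e.g.
    collinear points for superposition, a zero-edge unit cell)."""


class FitError(UbrecError):
    """A model fit could not be attempted on the given data."""


class UndefinedEfficiencyError(UbrecError):
    """Growth efficiency was requested for a no-significant-growth fit."""
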