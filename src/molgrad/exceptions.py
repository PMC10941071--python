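"""Exception hierarchy shared across the package.

Argument-contract violations raise plain :class:`ValueError`; data that is
structurally valid but statistically unusable raises one of the subclasses
below so callers can distinguish "you called it wrong" from "your data
cannot support this computation".
"""


class MolgradError(Exception):
    """Base class for package-specific errors."""


class InvalidDataError(MolgradError, ValueError):
    """Input tables are well-formed but violate a statistical precondition
    (empty stratum, rank-deficient design, disconnected graph, ...)."""


class DegenerateParcelError(InvalidDataError):
    """One or more parcels carry no usable signal (zero variance / zero row)."""

    def __init__(self, message: str, parcels=None):
        super().__init__(message)
        self.parcels = list(parcels) if parcels is not None else []


class DegenerateInputError(InvalidDataError):
    """A vector input has no variance, so a correlation is undefined."""
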