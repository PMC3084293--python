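"""Exception types shared across the package."""


class NrxGeomError(Exception):
    """Base class for all package errors."""


class ParseError(NrxGeomError):
    """A coordinate file could not be parsed."""


class FormatError(NrxGeomError):
    """An unknown or unsupported file format was requested."""


class EmptySelectionError(NrxGeomError):
    """A domain selection matched no residues."""


class DegenerateInputError(NrxGeomError):
    """Geometric input is degenerate (too few points, collinear, zero axis...)."""


class MissingRadiusError(NrxGeomError):
    """An atom has no entry in the van der Waals radii table."""
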