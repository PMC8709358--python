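"""Exception hierarchy shared across the package."""


class GammasecError(Exception):
    """Base class for all package errors."""


class UnknownCatalogError(GammasecError, KeyError):
    """Requested mutation catalog name is not shipped."""


class PositionRangeError(GammasecError, ValueError):
    """Residue position falls outside a sequence window."""


class WildtypeMismatchError(GammasecError, ValueError):
    """Declared wild-type residue disagrees with the window sequence."""


class DisorderParseError(GammasecError, ValueError):
    """Malformed disorder-profile file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(GammasecError, ValueError):
    """Invalid parameter set (scorer scale, thresholds, region ranges)."""


class AlignmentError(GammasecError, ValueError):
    """Profiles cannot be aligned (length or start mismatch)."""


class EmptyInputError(GammasecError, ValueError):
    """Operation requires a non-empty input."""


class GeometryError(GammasecError, ValueError):
    """Impossible membrane/protein geometry."""


class StructureFormatError(GammasecError, ValueError):
    """Coordinate file could not be parsed."""


class EmptyModelError(GammasecError, ValueError):
    """Coordinate file contains no usable (non-water, non-hydrogen) atoms."""


class ChainError(GammasecError, KeyError):
    """Requested chain absent from the structure."""


class SelectionError(GammasecError, ValueError):
    """Atom selection resolves to too few atoms for the operation."""


class RegionError(GammasecError, ValueError):
    """Named region does not resolve on the structure."""


class SpecError(GammasecError, ValueError):
    """Invalid synthetic-fixture specification."""
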