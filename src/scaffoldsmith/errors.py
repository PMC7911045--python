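"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, data/format errors -> 3,
anything else -> 1.
"""


class ScaffoldError(Exception):
    """Base class for all package errors."""


class InputError(ScaffoldError):
    """A caller violated a documented precondition."""


class ParseError(ScaffoldError):
    """A file could not be read in the named format."""


class FormatError(ParseError):
    """A file parsed but its content violates the dialect (missing rows, bad tokens)."""


class EmptyModelError(ParseError):
    """A structure file contained no polymer residues."""


class MappingError(ScaffoldError):
    """Sequence-to-structure mapping failed (alignment identity too low)."""


class DegenerateGeometryError(ScaffoldError):
    """Point sets too degenerate (collinear/coincident) for superposition."""


class AssemblyError(ScaffoldError):
    """Cassette assembly validation failed."""


class ConfigError(ScaffoldError):
    """Pipeline configuration invalid; reported before any computation."""
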