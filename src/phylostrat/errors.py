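"""Exception hierarchy.

Two broad classes matter to callers: :class:`PhylostratError` subclasses that
indicate invalid inputs or configuration (CLI exit code 2) and ordinary
I/O failures (exit code 3, raised as :class:`OSError` by the standard
library and passed through).
"""


class PhylostratError(Exception):
    """Base class for all package-specific errors."""


class NewickParseError(PhylostratError):
    """Malformed Newick text; message names the approximate character offset."""


class TreeValidationError(PhylostratError):
    """Tree violates a structural invariant (duplicate labels, bad ages ...)."""


class DatingError(TreeValidationError):
    """A child node is dated older than its parent."""


class UnknownLeafError(PhylostratError, KeyError):
    """A requested leaf / node label is not present in the tree."""

    def __str__(self) -> str:  # KeyError quotes its args; keep plain message
        return Exception.__str__(self)


class FormatError(PhylostratError):
    """A tabular input file violates its column layout; names the line."""


class PartitionError(PhylostratError):
    """A protein is claimed by more than one family."""


class CoverageError(PhylostratError):
    """Family database cites species absent from the species tree."""


class UnassignedProteinError(PhylostratError, KeyError):
    """The protein belongs to no family in the database."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class ArgumentError(PhylostratError, ValueError):
    """An argument is outside its documented domain."""


class EmptyInputError(PhylostratError):
    """A protein list or feature table resolved to nothing usable."""


class DegenerateInputError(PhylostratError):
    """Statistic undefined on this input (constant values, empty background)."""


class SizeError(PhylostratError):
    """Problem too large for an exhaustive (oracle) routine."""
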