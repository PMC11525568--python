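"""Exception hierarchy shared across the package."""


class RelaxkitError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(RelaxkitError):
    """A delimited table does not conform to the expected dialect."""


class DuplicateResidueError(TableFormatError):
    """The same residue label appears more than once in a table."""


class ConsistencyError(RelaxkitError):
    """Records that must agree (observable kind, residue, field) do not."""


class InsufficientDataError(RelaxkitError):
    """Too few data points or residues for the requested operation."""


class UndefinedCorrelationError(RelaxkitError):
    """Correlation requested on a vector with zero variance."""


class PDBFormatError(RelaxkitError):
    """Unsupported or malformed PDB content (e.g. insertion codes)."""


class ConfigError(RelaxkitError):
    """Invalid pipeline or simulation configuration."""
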