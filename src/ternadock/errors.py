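"""Exception hierarchy for ternadock.

Every contract violation raises a subclass of :class:`TernadockError` so
callers (and the CLI) can distinguish user error from numerical failure.
"""


class TernadockError(Exception):
    """Base class for all ternadock errors."""


class FormatError(TernadockError):
    """A structure or ligand file could not be parsed."""


class SelectorError(TernadockError):
    """A requested chain, residue, or ligand is absent from the file."""


class ConformerError(TernadockError):
    """Distance-geometry embedding of a ligand failed."""


class ContractError(TernadockError):
    """An operation was called with arguments violating its preconditions."""


class DegenerateGeometryError(TernadockError):
    """Point sets are too degenerate (collinear / coincident) for rigid fitting."""


class MetricError(TernadockError):
    """A score is undefined for the given structures (e.g. no native contacts)."""


class NumericError(TernadockError):
    """A non-finite value appeared inside the network forward/backward pass."""


class ConfigError(TernadockError):
    """A configuration file or value failed validation."""
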