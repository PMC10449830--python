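"""Exception hierarchy shared across the package."""


class ClonoshiftError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(ClonoshiftError):
    """Invalid configuration (unknown dialect, infeasible simulation config...)."""


class FormatError(ClonoshiftError):
    """A table does not match the expected column layout."""


class DataError(ClonoshiftError):
    """Input data violate an operation's preconditions (empty table, unnormalized
    frequencies, missing gene calls...)."""


class StatsError(ClonoshiftError):
    """A statistical routine cannot run on the supplied data (degenerate input,
    too few events, non-convergence)."""
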