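"""Exception and warning types used across the package."""


class RartrialError(Exception):
    """Base class for all package-specific errors."""


class InvalidPriorError(RartrialError, ValueError):
    """Raised when a prior specification is invalid (e.g. non-positive sigma)."""


class GridError(RartrialError, ValueError):
    """Raised when a quadrature grid fails to contain the posterior mass."""


class DegenerateAllocationError(RartrialError, ValueError):
    """Raised when every raw allocation weight is zero."""


class BlockRoundingError(RartrialError, ValueError):
    """Raised when allocation weights cannot be represented at the block size."""


class ConfigError(RartrialError, ValueError):
    """Raised when a design or scenario configuration is invalid."""


class SamplerWarning(UserWarning):
    """Emitted when an MCMC run shows poor mixing (low effective sample size)."""
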