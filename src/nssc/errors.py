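"""Exception hierarchy shared across the package."""


class NSSCError(Exception):
    """Base class for all package errors."""


class ConfigError(NSSCError):
    """Invalid scenario/run configuration (bad file, bad key, bad value)."""


class NumericalError(NSSCError):
    """A numerical computation failed (singular system, non-convergence)."""


class UnreachableAbsorptionError(NumericalError):
    """The coalesced state cannot be reached from the initial configuration,
    so the coalescence time is defective (infinite with positive probability)."""


class StateSpaceTooLargeError(NSSCError):
    """The (k, n) state space exceeds the configured size cap."""
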