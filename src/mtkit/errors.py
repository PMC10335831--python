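"""Exception types shared across the toolkit."""


class MtkError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(MtkError, ValueError):
    """A configuration value is invalid (non-finite, out of range, unknown key)."""


class TrajectoryError(MtkError, ValueError):
    """A trajectory violates its structural invariants."""


class NeverMotileError(MtkError):
    """No interval of the trajectory ever reaches the pause/transport speed threshold."""


class UndefinedResultError(MtkError):
    """The requested quantity is undefined for this input (e.g. featureless kymograph)."""


class InsufficientDataError(MtkError, ValueError):
    """Too few observations for the requested statistic."""
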