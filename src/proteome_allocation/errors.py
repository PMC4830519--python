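"""Exception hierarchy for the package."""


class ProteomeAllocationError(Exception):
    """Base class for all package errors."""


class ModelInvalidError(ProteomeAllocationError):
    """An AffinityModel violates a structural invariant (e.g. W_B = 0)."""


class DegenerateConditionError(ProteomeAllocationError):
    """A condition carries zero total affinity — fractions are undefined."""


class UndefinedStatisticError(ProteomeAllocationError):
    """A statistic is undefined for the given input (too few values, zero variance)."""


class InsufficientDataError(ProteomeAllocationError):
    """Filtering or analysis left too little data to proceed."""


class ConfigError(ProteomeAllocationError):
    """Invalid configuration value or combination."""
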