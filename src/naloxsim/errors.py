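"""Exception types used across the simulator."""


class NaloxsimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NaloxsimError, ValueError):
    """A parameter set or configuration file is invalid.

    The message names the offending field wherever possible.
    """


class DomainError(NaloxsimError, ValueError):
    """A numerical argument is outside the mathematical domain of an operation."""


class ValidationError(ConfigurationError):
    """A scenario/config document failed schema validation."""
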