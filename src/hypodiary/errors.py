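"""Exception types shared across the pipeline."""


class HypodiaryError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HypodiaryError):
    """Bad run configuration: missing columns, unreadable dialect, invalid options."""


class ContractViolation(HypodiaryError):
    """A function was handed an object that violates its preconditions
    (e.g. an unregularised trace passed to the episode detector)."""


class UndefinedStatisticError(HypodiaryError):
    """A summary is undefined for the given input (all-missing trace,
    zero-length interval, zero intercept in a percent-change transform)."""


class CodingError(HypodiaryError):
    """A raw diary answer could not be mapped onto a known subtype level."""


class EstimationError(HypodiaryError):
    """Model estimation is impossible on the given data (single participant,
    fewer than two observed exposure levels)."""
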