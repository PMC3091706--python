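"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: configuration errors -> 2, parse errors -> 3,
computation errors -> 4 (see :mod:`coexnet.cli`).
"""

__all__ = [
    "CoexnetError",
    "ConfigurationError",
    "ParseError",
    "ComputationError",
    "EmptyResultError",
    "InsufficientDataError",
    "DegenerateDistributionError",
    "UndefinedMetricError",
]


class CoexnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CoexnetError):
    """Invalid parameters, thresholds or file layout in a configuration."""


class ParseError(CoexnetError):
    """Malformed input file; message names the offending location."""


class ComputationError(CoexnetError):
    """A computation could not produce a defined result."""


class EmptyResultError(ComputationError):
    """An operation removed every row / produced an empty output."""


class InsufficientDataError(ComputationError):
    """Too few samples or observations for the requested statistic."""


class DegenerateDistributionError(ComputationError):
    """A distribution lacks enough distinct values for the requested fit."""


class UndefinedMetricError(ComputationError):
    """A graph metric is undefined on the given input (e.g. no connected pair)."""
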