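"""Exception hierarchy.

All trajstat errors derive from :class:`TrajstatError` so callers can catch
the whole family; the subclasses mirror the distinct failure contracts of the
I/O, statistics and simulation layers.
"""


class TrajstatError(Exception):
    """Base class for all trajstat errors."""


class TimeRangeError(TrajstatError):
    """A query time lies before the first recorded time point."""


class VariableNameError(TrajstatError, KeyError):
    """An unknown, duplicate or reserved variable name was requested."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return Exception.__str__(self)


class FormatError(TrajstatError):
    """A delimited text file violates the trajectory format."""


class ConsistencyError(TrajstatError):
    """Members of a dataset disagree on shape or variable names."""


class EmptyDatasetError(TrajstatError):
    """A dataset directory matched no files, or an ensemble is empty."""


class UnsupportedDialectError(TrajstatError):
    """An SBRML file uses a layout outside the supported time-course subset."""


class ParameterError(TrajstatError, ValueError):
    """An operation parameter is out of its valid domain."""


class ModelError(TrajstatError):
    """A reaction model is ill-formed (e.g. negative propensity)."""
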