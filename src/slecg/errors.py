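"""Exception hierarchy shared across the pipeline.

Plain ``ValueError`` is used for bad arguments to individual operations;
the classes here mark problems with input files or configuration, which
the command-line layer maps to distinct exit codes.
"""


class SlecgError(Exception):
    """Base class for pipeline-specific errors."""


class ConfigurationError(SlecgError):
    """Invalid or incomplete configuration (unknown wavelet, missing fs, ...)."""


class FormatError(SlecgError):
    """A file could not be parsed in the requested format."""


class DataError(SlecgError):
    """A file parsed but its contents violate signal invariants."""
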