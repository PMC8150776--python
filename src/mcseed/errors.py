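"""Exception hierarchy shared across the pipeline stages."""


class McseedError(Exception):
    """Base class for all package errors."""


class ConfigurationError(McseedError):
    """Invalid configuration: missing libraries, bad thresholds, absent files."""


class FormatError(McseedError):
    """Malformed input file: bad columns, duplicate positions, non-numeric counts."""


class DataError(McseedError):
    """Data violates a runtime requirement (e.g. zero-count library)."""


class StateError(McseedError):
    """Operation called on an object in the wrong state (e.g. unnormalized matrix)."""
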