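"""Exception types shared across the pipeline."""


class VineclimError(Exception):
    """Base class for pipeline errors."""


class InvalidParameterError(VineclimError, ValueError):
    """A configuration or function parameter is outside its valid domain."""


class InputFormatError(VineclimError, ValueError):
    """An input table violates the documented schema (ordering, duplicates, columns)."""


class OutOfBoundsError(VineclimError, ValueError):
    """A point location falls outside the covariate grid extent."""


class InsufficientDataError(VineclimError, ValueError):
    """Too few observations to fit or evaluate (e.g. < 30 paired days for a correction)."""


class UndefinedResultError(VineclimError, ValueError):
    """The requested quantity is undefined on this input (e.g. empty index window)."""


class ConfigurationError(VineclimError, ValueError):
    """Mismatched or missing model/schema configuration between pipeline stages."""
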