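"""Exception hierarchy shared across the pipeline."""


class LibsClassError(Exception):
    """Base class for all package errors."""


class SpectraFormatError(LibsClassError, ValueError):
    """A spectral table could not be parsed (bad header, duplicate columns...)."""


class DimensionError(LibsClassError, ValueError):
    """Shapes, masks or grids are incompatible with the requested operation."""


class NormalizationError(LibsClassError, ValueError):
    """Reference-line normalization failed for one or more spectra.

    Carries the offending row indices in ``rows``.
    """

    def __init__(self, message: str, rows=()):
        super().__init__(message)
        self.rows = tuple(rows)


class ClassSizeError(LibsClassError, ValueError):
    """A per-class operation found a class with too few rows; names the class."""

    def __init__(self, message: str, class_name: str = ""):
        super().__init__(message)
        self.class_name = class_name


class BatchCorrectionError(LibsClassError, RuntimeError):
    """Row-wise baseline correction failed for some rows; carries their indices."""

    def __init__(self, message: str, rows=()):
        super().__init__(message)
        self.rows = tuple(rows)


class ConfigError(LibsClassError, ValueError):
    """A pipeline configuration file is malformed or inconsistent."""
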