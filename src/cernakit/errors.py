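"""Exception hierarchy shared across the package."""


class CernakitError(Exception):
    """Base class for all package-specific errors."""


class InvalidSymbolError(CernakitError):
    """A gene symbol is empty or unparseable."""


class EmptyGeneSetError(CernakitError):
    """A gene list parsed to zero symbols."""


class CategoryMismatchError(CernakitError):
    """Gene sets of different categories were merged."""


class DataError(CernakitError):
    """Input data violates a structural precondition (e.g. negative counts)."""


class DesignError(CernakitError):
    """Experimental design is insufficient (e.g. a group with <2 samples)."""


class DegenerateDataError(CernakitError):
    """Data carries no usable signal (e.g. all variances zero)."""


class ConfigError(CernakitError):
    """Invalid configuration value."""


class FormatError(CernakitError):
    """A file or record violates the expected format."""
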