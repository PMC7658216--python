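"""Exception hierarchy."""


class NBudgetError(Exception):
    """Base class for all package errors."""


class ValidationError(NBudgetError):
    """An input value violates a documented precondition (e.g. negative population)."""


class VocabularyError(NBudgetError):
    """An unknown land-use class or budget item name."""


class CoefficientGapError(NBudgetError):
    """A category present in the activity data has no coefficient entry."""


class GridIncompatibleError(NBudgetError):
    """Two rasters do not share shape/transform and cannot be combined."""


class AssemblyError(NBudgetError):
    """A region is missing activity data required for a mandatory budget item."""


class ConfigError(NBudgetError):
    """A run configuration is incomplete or references missing files."""
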