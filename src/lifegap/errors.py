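"""Exception hierarchy for the lifegap pipeline."""


class LifegapError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(LifegapError):
    """An invalid scenario or pipeline configuration value (names the field)."""


class ValidationError(LifegapError):
    """Structurally invalid input data (missing cells, unknown labels, ...)."""


class DegenerateInputError(LifegapError):
    """Numerically degenerate input: zero variance, rank-deficient PCA,
    zero open-interval rate, constant regressor."""


class CompletenessError(LifegapError):
    """A period window is missing required years, bands or cells."""


class InsufficientDataError(LifegapError):
    """Too few matched observations to fit the requested model."""


class ParseError(LifegapError):
    """A malformed input file; the message cites the offending line(s)."""
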