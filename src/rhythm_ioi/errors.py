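"""Exception hierarchy shared across the package."""


class RhythmIOIError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RhythmIOIError, ValueError):
    """Invalid configuration value or combination."""


class ValidationError(RhythmIOIError, ValueError):
    """Input data violates a structural invariant."""


class FormatError(RhythmIOIError, ValueError):
    """A file does not conform to its declared format."""


class TierNotFoundError(FormatError, KeyError):
    """The requested TextGrid tier does not exist."""


class UntestableDatasetError(RhythmIOIError, ValueError):
    """Too few inter-onset-interval ratios to run the permutation test."""


class EmptySubsetError(RhythmIOIError, ValueError):
    """A pair-restricted analysis selected zero qualifying ratios."""
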