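"""Exception and warning types shared across the package."""


class ColorbiasError(Exception):
    """Base class for all package errors."""


class EmbeddingFormatError(ColorbiasError):
    """Malformed embedding file (bad header, ragged rows, duplicate words)."""


class LexiconFormatError(ColorbiasError):
    """Malformed lexicon file (empty effective list, interior wildcard)."""


class LexiconResolutionError(ColorbiasError):
    """A lexicon resolved to zero vocabulary words."""


class DegenerateConceptError(ColorbiasError):
    """A concept mean vector (or a scored vector) is zero."""


class DegenerateSpaceError(ColorbiasError):
    """A synthetic configuration with no signal and no noise."""


class ConfigurationError(ColorbiasError):
    """Inconsistent run configuration (e.g. an axis naming an unknown concept)."""


class LexiconCoverageWarning(UserWarning):
    """Some lexicon patterns did not resolve against the vocabulary."""
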