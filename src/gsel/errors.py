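"""Exception hierarchy for gsel."""


class GselError(Exception):
    """Base class for all gsel errors."""


class ConfigurationError(GselError):
    """Invalid configuration or parameter values."""


class FormatError(GselError):
    """Unparseable or malformed input file."""


class EmptyInputError(GselError):
    """An operation received or produced zero usable records."""


class DesignError(GselError):
    """Invalid model design (singular fixed effects, mismatched shapes...)."""


class MatrixError(GselError):
    """A required matrix property (PSD, invertibility) does not hold."""


class DegenerateInputError(GselError):
    """Input with no usable variation (e.g. constant phenotypes)."""


class InsufficientDataError(GselError):
    """Not enough records/replicates/draws for the requested estimate."""


class SelectionError(GselError):
    """Invalid selection request (k too large, empty candidate set...)."""
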