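"""Exception types shared across the package."""


class BenthofindError(Exception):
    """Base class for package errors."""


class ConfigurationError(BenthofindError, ValueError):
    """A configuration object failed validation; the message names the field."""


class ArgumentError(BenthofindError, ValueError):
    """An operation received an invalid argument."""


class TrainingDivergenceError(BenthofindError, RuntimeError):
    """Model training produced a non-finite loss; the message names the epoch."""


class DegenerateInputError(BenthofindError, ValueError):
    """Input is degenerate for the requested computation (e.g. rank-0 matrix)."""
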