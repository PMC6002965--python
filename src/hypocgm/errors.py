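"""Exception hierarchy shared across the package.

Every stage fails fast with one of these; nothing is silently imputed,
clipped or skipped.
"""


class HypocgmError(Exception):
    """Base class for all package errors."""


class ConfigError(HypocgmError):
    """Invalid generator / pipeline configuration."""


class InputError(HypocgmError):
    """Invalid input data (wrong subject, negative seed, bad category, ...)."""


class SchemaError(InputError):
    """A CSV file violates its documented schema; message carries row/column."""


class InsufficientDataError(InputError):
    """Too few samples to compute the requested quantity."""


class DegenerateInputError(InputError):
    """Statistically degenerate input (zero variance, empty margin, ...)."""


class NonConvergenceError(HypocgmError):
    """A model fit did not converge / separated; never reported silently."""
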