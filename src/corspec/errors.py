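"""Exception hierarchy.

Two broad families matter to callers (and to the command-line exit codes):
input/configuration problems (``InputError`` and subclasses) versus numerical
failures of the fitting machinery (``NumericalError`` and subclasses).
"""


class CorspecError(Exception):
    """Base class for all package errors."""


class ConfigError(CorspecError, ValueError):
    """A configuration value is invalid; the message names the field."""


class InputError(CorspecError, ValueError):
    """Malformed or inconsistent user-supplied data."""


class MissingBaselineError(InputError):
    """No vehicle (dose 0) rows available for normalization."""


class DegenerateBaselineError(InputError):
    """Vehicle mean is zero or negative; fold-activation is undefined."""


class ParseError(InputError):
    """A FASTA/newick/CSV stream could not be parsed."""


class NumericalError(CorspecError, RuntimeError):
    """Numerical failure in model fitting."""


class NonConvergenceError(NumericalError):
    """No optimizer start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class NoActivationError(NumericalError):
    """Series is flat at baseline; EC50 is undefined."""
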