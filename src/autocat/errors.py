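"""Exception hierarchy shared across the package."""


class AutocatError(Exception):
    """Base class for all package errors."""


class NetworkParseError(AutocatError, ValueError):
    """A network file could not be parsed; the message names the record."""


class ValidationError(AutocatError, ValueError):
    """Input violates a documented precondition or type invariant."""


class DomainError(AutocatError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation.

    Raised instead of clipping: the stability analysis is sign-sensitive,
    so silently coercing a negative concentration could flip a verdict.
    """


class NotSteadyStateError(AutocatError, ValueError):
    """Supplied concentrations do not satisfy the steady-state equations."""
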