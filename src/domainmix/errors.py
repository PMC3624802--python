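"""Exception hierarchy for domainmix."""


class DomainmixError(Exception):
    """Base class for all domainmix errors."""


class InvalidProfileError(DomainmixError, ValueError):
    """A domain profile violates its invariants (negative, all-zero, ...)."""


class AlignmentError(DomainmixError, ValueError):
    """Profile and signature matrix are not on the same family universe."""


class ParseError(DomainmixError, ValueError):
    """A TSV input is malformed; the message names the file and line."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class FitDegenerateError(DomainmixError, ValueError):
    """No observed domain family is supported by any reference signature."""

    def __init__(self, unsupported_mass):
        self.unsupported_mass = float(unsupported_mass)
        super().__init__(
            "mixture fit is degenerate: all observed domain-hit mass "
            f"({self.unsupported_mass:.6g}) lies outside the support of every "
            "reference signature"
        )


class SelectionError(DomainmixError, ValueError):
    """Invalid input to the signature-selection procedure."""


class EliminationAborted(DomainmixError, RuntimeError):
    """Stepwise elimination stopped because a class would become too small.

    Carries the partial :class:`~domainmix.selection.SelectionResult` built
    up to the aborted round.
    """

    def __init__(self, message, partial_result):
        self.partial_result = partial_result
        super().__init__(message)
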