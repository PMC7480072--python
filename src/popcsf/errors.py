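"""Exception hierarchy.

Exit-code mapping at the CLI: :class:`ValidationError` -> 2,
:class:`DegenerateError` -> 3, anything else -> 1.
"""


class PopCSFError(Exception):
    """Base class for all popcsf errors."""


class DomainError(PopCSFError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(PopCSFError, ValueError):
    """Structured input failed validation.

    Carries the full list of failures, not only the first one.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DegenerateError(PopCSFError, ArithmeticError):
    """A numerical degeneracy (e.g. an all-zero posterior after an update)."""


class FalseAlarmUpdateError(PopCSFError, ValueError):
    """A false alarm was passed to the Bayesian update.

    False alarms carry no stimulus information and must never enter the
    posterior; the caller is responsible for filtering them out.
    """
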