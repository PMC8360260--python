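"""Exception hierarchy shared across the package.

All validation failures raise :class:`ValidationError` (invalid argument,
schema violation, missing data); numerical failures (non-convergent fits)
raise :class:`NumericalError`.  The CLI maps these to exit codes 2 and 3.
"""


class RicdosimError(Exception):
    """Base class for all package errors."""


class ValidationError(RicdosimError, ValueError):
    """Invalid argument, malformed table, or violated invariant."""


class SchemaError(ValidationError):
    """A delimited-text table does not match its documented schema."""


class MissingDataError(ValidationError):
    """A required organ, row, mass or table entry is absent."""


class MissingSValueError(MissingDataError):
    """A source organ has no entry in the S-value table."""

    def __init__(self, organs):
        self.organs = sorted(organs)
        super().__init__(f"no S-value entry for source organ(s): {', '.join(self.organs)}")


class RangeError(ValidationError):
    """A query falls outside the tabulated range (e.g. sphere mass)."""


class NumericalError(RicdosimError, RuntimeError):
    """A numerical procedure failed (non-convergence, boundary-pinned fit)."""


class FitFailureError(NumericalError):
    """Least-squares fit did not converge or is pinned at a bound."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
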