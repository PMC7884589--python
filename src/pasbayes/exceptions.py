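"""Exception hierarchy for the pasbayes pipeline.

Exit-code mapping used by the CLI: validation errors (schema, configuration,
input) exit 2, numerical failures exit 3, I/O failures exit 4.
"""


class PasBayesError(Exception):
    """Base class for all pasbayes errors."""


class ConfigurationError(PasBayesError, ValueError):
    """A configuration field is invalid; the message names the field."""


class InputError(PasBayesError, ValueError):
    """Input data violate a precondition of an operation."""


class SchemaError(InputError):
    """A trial table fails schema validation; carries offending row indices."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = list(rows) if rows is not None else []


class UndefinedStatisticError(InputError):
    """A statistic is undefined for the given data (e.g. zero variance)."""


class ImputationError(PasBayesError):
    """Imputation cannot proceed (e.g. no complete donor rows)."""


class NumericalError(PasBayesError):
    """A numerical routine failed to converge; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class PipelineError(PasBayesError):
    """An end-to-end pipeline invariant is violated."""
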