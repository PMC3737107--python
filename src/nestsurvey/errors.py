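"""Exception hierarchy.

SchemaError covers malformed input files and configuration; NumericalError
covers optimizer failures and degenerate estimation problems.  The CLI maps
them to exit codes 2 and 3 respectively.
"""


class NestSurveyError(Exception):
    """Base class for package errors."""


class SchemaError(NestSurveyError):
    """Invalid input file, column, row or configuration value."""


class NumericalError(NestSurveyError):
    """Estimation failed: non-convergence, degenerate data, bad bounds."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
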