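"""Package-wide exception types."""


class MismapError(Exception):
    """Base class for all package errors."""


class FormatError(MismapError):
    """Malformed or mutually inconsistent input files."""


class QCError(MismapError):
    """Quality control removed everything (the report is attached)."""

    def __init__(self, message, report=None):
        super().__init__(message)
        self.report = report
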