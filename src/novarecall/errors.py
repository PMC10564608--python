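"""Exception hierarchy shared across the package.

Every error raised by the library derives from :class:`NovaRecallError` so
callers (and the CLI) can distinguish library failures from programming bugs.
"""


class NovaRecallError(Exception):
    """Base class for all novarecall errors."""


class SchemaError(NovaRecallError):
    """A bundle file violates the documented schema.

    Carries the offending file, record and the rule that failed so load
    errors are actionable.
    """

    def __init__(self, file: str, record: str, rule: str):
        self.file = file
        self.record = record
        self.rule = rule
        super().__init__(f"{file}: record {record!r}: {rule}")


class IntegrityError(NovaRecallError):
    """Referential integrity is broken (dangling code, missing recipe...)."""


class ContractError(NovaRecallError):
    """An operation was called outside its precondition."""


class StateError(NovaRecallError):
    """A recall session is in an inconsistent state (e.g. an answer recorded
    for a question whose trigger is not satisfied)."""


class IncompleteSessionError(NovaRecallError):
    """Finalization attempted with mandatory questions unanswered."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(
            "session cannot be finalized; unanswered questions: "
            + ", ".join(self.missing)
        )


class ProcessingError(NovaRecallError):
    """A completed session could not be turned into consumption records."""


class ImputationError(ProcessingError):
    """No population distribution available for a missing field and no
    fallback was configured."""


class DegenerateDataError(NovaRecallError):
    """Statistical input is degenerate (e.g. zero variance everywhere)."""
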