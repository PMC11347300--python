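"""Exception hierarchy for pupilgate."""


class PupilgateError(Exception):
    """Base class for all pupilgate errors."""


class ConfigError(PupilgateError, ValueError):
    """A configuration value violates its invariant; the message names the field."""


class SizingError(PupilgateError, ValueError):
    """An input is too small/large for the requested operation (reports required vs available)."""


class DataError(PupilgateError, ValueError):
    """Malformed or degenerate data (parse failures, all-invalid series, zero variance)."""


class StageError(PupilgateError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
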