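"""Exception hierarchy shared across the pipeline stages."""


class SldepError(Exception):
    """Base class for all package errors."""


class ValidationError(SldepError, ValueError):
    """Input violates a documented contract (bad value, bad table, bad name)."""


class GroupSizeError(ValidationError):
    """A statistical test received fewer observations than it requires."""


class DegenerateInputError(ValidationError):
    """Input is formally valid but statistically degenerate (zero variance,
    constant vector, equal control medians)."""


class ConfigurationError(SldepError, ValueError):
    """A run/stage configuration is inconsistent or infeasible."""


class ParseError(SldepError, ValueError):
    """A text input file does not conform to its documented dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class StageError(SldepError, RuntimeError):
    """A pipeline stage failed; carries the stage name for exit reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
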