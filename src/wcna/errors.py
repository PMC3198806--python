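"""Exception hierarchy.

``InputError`` marks problems with user-supplied data or parameters and maps
to exit code 1 in the CLI; anything else is treated as an internal error
(exit code 2).
"""


class WcnaError(Exception):
    """Base class for all package errors."""


class InputError(WcnaError, ValueError):
    """Invalid user input: malformed table, bad parameter, missing sample."""


class PipelineError(WcnaError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
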