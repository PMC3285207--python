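"""Exception hierarchy.

Everything raised on purpose derives from :class:`ComirnetError` so callers
(and the CLI) can separate user/configuration problems from genuine bugs.
"""


class ComirnetError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ComirnetError, ValueError):
    """A parameter violates its documented domain; the message names the bound."""


class DataError(ComirnetError, ValueError):
    """Input data violates a precondition (missing values, empty intersection...)."""


class LookupFailure(ComirnetError, KeyError):
    """An identifier was not found where the contract requires it."""


class PipelineError(ComirnetError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
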