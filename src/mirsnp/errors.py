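"""Exception hierarchy shared across the pipeline.

``MirsnpError`` subclasses carry a ``stage`` attribute so the CLI can
distinguish user-input problems (exit 1) from internal failures (exit 2).
"""


class MirsnpError(Exception):
    """Base class for all package errors."""

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        super().__init__(message if stage is None else f"[{stage}] {message}")


class ParseError(MirsnpError):
    """Malformed input file (carries a line number where known)."""


class AlphabetError(MirsnpError):
    """Sequence contains characters outside the declared alphabet."""


class ParameterError(MirsnpError):
    """Invalid parameter combination or out-of-contract argument."""


class PedigreeError(MirsnpError):
    """Structurally broken pedigree (e.g. unresolvable parent id)."""
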