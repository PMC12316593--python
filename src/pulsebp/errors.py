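"""Exception hierarchy shared across the package."""


class PulseBpError(Exception):
    """Base class for all package errors."""


class FormatError(PulseBpError):
    """A file or record does not conform to the expected layout."""


class ParseError(FormatError):
    """Non-numeric or otherwise unreadable sample data."""


class InvalidRecordError(PulseBpError):
    """A waveform record violates a structural invariant (e.g. fs <= 0)."""


class InsufficientBeatsError(PulseBpError):
    """An operation requires more beats/intervals than were supplied."""


class InvalidInputError(PulseBpError):
    """Numerically invalid input (e.g. zero mean R-R interval)."""


class ConfigError(PulseBpError):
    """Invalid pipeline or simulation configuration."""


class StageError(PulseBpError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
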