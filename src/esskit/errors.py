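"""Exception hierarchy shared across esskit."""


class EssError(Exception):
    """Base class for all esskit errors."""


class HedParseError(EssError):
    """A HED tag string could not be parsed; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)
        self.position = position


class VocabularyError(EssError):
    """The HED vocabulary document is structurally invalid."""


class ManifestError(EssError):
    """A study manifest could not be read or is structurally unusable."""


class BuildError(EssError):
    """Container assembly failed (validation errors, missing sources, ...)."""


class SignalError(EssError):
    """A signal-processing precondition was violated."""
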