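"""Exception types shared across the package."""


class OxiswitchError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(OxiswitchError, ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


class StageError(OxiswitchError, RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
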