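"""Exception hierarchy shared across the package."""


class PairTcrError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PairTcrError, ValueError):
    """A file does not conform to the expected on-disk format."""


class DimensionError(PairTcrError, ValueError):
    """Declared dimensions disagree with sidecar tables or data."""


class InvariantError(PairTcrError, ValueError):
    """An in-memory object violates one of its stated invariants."""


class ConfigError(PairTcrError, ValueError):
    """A configuration object is inconsistent or incomplete."""


class StageError(PairTcrError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage:{stage}] {message}")
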