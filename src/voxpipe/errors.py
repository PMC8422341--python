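"""Exception hierarchy.

Every user-facing failure derives from :class:`VoxPipeError` so the CLI and the
batch engine can distinguish expected processing errors from genuine bugs.
"""


class VoxPipeError(Exception):
    """Base class for all voxpipe errors."""


class ProtocolError(VoxPipeError):
    """Malformed protocol text. Carries the 1-based source line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class KeywordError(ProtocolError):
    """Unknown ``?token?`` keyword in a parameter value."""


class RegistryError(VoxPipeError):
    """Bad registry file or duplicate module name."""


class StoreError(VoxPipeError):
    """Image/table database failure (missing image, bad path, malformed CSV)."""


class ModuleError(VoxPipeError):
    """A module invocation failed: bad parameters or a processing error."""


class FixtureError(VoxPipeError):
    """Synthetic-scene generation could not satisfy its constraints."""
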