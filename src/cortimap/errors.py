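"""Exception hierarchy shared across cortimap modules."""


class CortimapError(Exception):
    """Base class for all cortimap errors."""


class FormatError(CortimapError):
    """A file does not conform to its declared on-disk layout."""


class ParseError(FormatError):
    """A text file failed to parse; carries the offending line/row."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class ValidationError(CortimapError):
    """Data parsed fine but violates a structural invariant."""


class ShapeError(ValidationError):
    """An array has the wrong shape for the requested interpretation."""


class DomainError(CortimapError, ValueError):
    """A parameter is outside its mathematical domain."""


class CameraError(CortimapError):
    """The camera state cannot define a valid view."""


class PlacementError(CortimapError):
    """Electrode placement failed (e.g. a strip ran off the surface)."""
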