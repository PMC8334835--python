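"""Exception types shared across the package."""


class OMRKitError(Exception):
    """Base class for all omrkit errors."""


class ConfigurationError(OMRKitError, ValueError):
    """Invalid apparatus, schedule or analysis configuration."""


class TrackFormatError(OMRKitError, ValueError):
    """A track file could not be parsed into a trajectory."""

    def __init__(self, message: str, path=None, row=None):
        ctx = []
        if path is not None:
            ctx.append(f"file={path}")
        if row is not None:
            ctx.append(f"row={row}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.path = path
        self.row = row


class InsufficientDataError(OMRKitError, ValueError):
    """Too few valid samples (or fish) to compute the requested quantity."""


class AlignmentError(OMRKitError, ValueError):
    """Track and epoch timelines do not cover each other."""
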