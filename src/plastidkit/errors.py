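"""Exception types shared across the package."""


class PlastidKitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlastidKitError, ValueError):
    """A file or sequence violates its format contract."""


class BoundsError(PlastidKitError, ValueError):
    """A coordinate or window falls outside the addressable range."""


class ParameterError(PlastidKitError, ValueError):
    """A numeric parameter violates its precondition."""


class StateError(PlastidKitError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class SizingError(PlastidKitError, ValueError):
    """A simulated genome is too short for the requested features."""


class OrientationError(PlastidKitError, ValueError):
    """A TSS/gene pair is inconsistent with transcription direction."""
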