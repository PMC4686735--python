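"""Exception hierarchy shared by all processing stages."""


class RetinaHazeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(RetinaHazeError):
    """Unsupported image format or bit depth."""


class ParameterError(RetinaHazeError, ValueError):
    """A model parameter violates its documented constraint."""


class RangeError(ParameterError):
    """Array values fall outside the range a stage requires."""


class GeometryError(RetinaHazeError, ValueError):
    """Kernel or stimulus geometry is incompatible with the target array."""


class DegenerateInputError(RetinaHazeError, ValueError):
    """Input on which the requested normalization is undefined (e.g. all-zero)."""


class StructuralError(RetinaHazeError, ValueError):
    """A required channel is missing or plane shapes disagree."""


class ConfigError(RetinaHazeError, ValueError):
    """Unknown or invalid configuration key."""
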