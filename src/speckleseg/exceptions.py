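"""Exception types shared across the package."""


class SpecklesegError(Exception):
    """Base class for package-specific errors."""


class DimensionError(SpecklesegError, ValueError):
    """Raised when array shapes are incompatible."""


class GeometryError(SpecklesegError, ValueError):
    """Raised when a requested geometry does not fit the image frame."""


class ConfigurationError(SpecklesegError, ValueError):
    """Raised for invalid parameter combinations."""


class NoSegmentationError(SpecklesegError, RuntimeError):
    """Raised when no usable segment can be extracted (trivial firing maps,
    no component above the minimum area, ...)."""
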