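"""Exception types shared across the package."""


class LayerFluenceError(Exception):
    """Base class for all package-specific errors."""


class InvalidMediumError(LayerFluenceError, ValueError):
    """Optical coefficients violate their physical constraints."""


class UnsupportedMediumError(LayerFluenceError, ValueError):
    """Medium is physically sensible but outside the implemented model
    (e.g. mismatched internal refractive indices)."""


class UnsupportedGeometryError(LayerFluenceError, ValueError):
    """Geometry violates a model precondition (e.g. source depth outside
    the top layer)."""


class DomainError(LayerFluenceError, ValueError):
    """Query point outside the admissible domain of an operation."""
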