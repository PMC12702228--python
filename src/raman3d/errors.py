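"""Exception hierarchy shared across the package."""


class Raman3DError(Exception):
    """Base class for all package errors."""


class FormatError(Raman3DError):
    """A container file is missing a required dataset/attribute."""


class ShapeError(Raman3DError):
    """Array extents are inconsistent with the declared layout."""


class ValidationError(Raman3DError):
    """A value violates a domain invariant (axis order, finiteness, range)."""


class ConfigError(Raman3DError):
    """A configuration value is out of its permitted range."""


class PlacementError(Raman3DError):
    """Phantom cells could not be placed without overlap within the retry budget."""


class EstimationError(Raman3DError):
    """Too little data to estimate noise-model parameters."""


class SplitError(Raman3DError):
    """A dataset cannot be partitioned with the requested fractions."""
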