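"""Exception hierarchy shared across the package."""


class PetStageError(Exception):
    """Base class for all package errors."""


class FormatError(PetStageError):
    """Input volume is not a usable 3-D image."""


class OrientationError(PetStageError):
    """Patient-axis orientations of PET and CT cannot be reconciled."""


class GeometryError(PetStageError):
    """Grid geometry violates a precondition (e.g. degenerate axis)."""


class ConfigurationError(PetStageError):
    """A configuration object is invalid or incomplete."""


class UndefinedMetricError(PetStageError):
    """A metric is undefined on the given data (e.g. no positive labels)."""


class UnknownClassError(PetStageError):
    """An anatomical class name is missing from the taxonomy."""
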