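"""Exception types raised across the pipeline."""


class BoutonQuantError(Exception):
    """Base class for all package errors."""


class StackFormatError(BoutonQuantError):
    """Channel grids disagree in shape/dtype, or a TIFF is malformed."""


class MissingChannelError(BoutonQuantError):
    """A required channel role is absent from the input."""


class InvalidMetadataError(BoutonQuantError):
    """Site metadata violates a physical constraint (thickness, exposure)."""


class InvalidParameterError(BoutonQuantError):
    """An algorithm parameter is out of its valid range."""


class GeometryError(BoutonQuantError):
    """Grids that must share dimensions do not."""


class OrientationError(BoutonQuantError):
    """The stack does not record which z end is the tissue surface."""


class DegenerateHistogramError(BoutonQuantError):
    """Otsu thresholding requested on a constant grid."""


class DegenerateDesignError(BoutonQuantError):
    """The study design cannot support the requested model fit."""


class InvalidSpecError(BoutonQuantError):
    """A simulation spec describes an impossible acquisition."""
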