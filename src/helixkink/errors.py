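"""Exception hierarchy for helixkink."""


class HelixKinkError(Exception):
    """Base class for all helixkink errors."""


class FormatError(HelixKinkError):
    """A coordinate or table file could not be parsed."""


class EmptyModelError(HelixKinkError):
    """A coordinate file contained no usable model/chains."""


class MissingBackboneError(HelixKinkError):
    """A residue inside a helix range lacks one of the N/CA/C/O atoms."""


class AnnotationError(HelixKinkError):
    """A helix annotation does not match the structure."""


class FitError(HelixKinkError):
    """Cylinder fitting failed (degenerate geometry or non-convergence)."""


class HelixTooShortError(HelixKinkError):
    """Angle measurement requires helices of at least 12 residues."""
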