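"""Exception hierarchy for the vcss package."""


class VcssError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(VcssError):
    """A structure file could not be parsed; names the offending line when known."""


class RosterError(VcssError):
    """Models within one trajectory do not share the same atom roster."""


class SelectionError(VcssError):
    """An atom selection did not resolve to exactly one atom."""


class GeometryError(VcssError):
    """A geometric computation is impossible (e.g. missing backbone atom)."""


class InsufficientFramesError(VcssError):
    """A sub-ensemble holds fewer frames than the number requested."""


class AnnotationError(VcssError):
    """A helix annotation references residues absent from the receptor."""


class EnergyTableError(VcssError):
    """A row of an external energy table is malformed; names the line."""


class ConstructionError(VcssError):
    """A synthetic geometry request is unreachable with the bead bond lengths."""


class LineshapeFitError(VcssError):
    """The Lorentzian least-squares fit failed to converge."""

    def __init__(self, message: str, residual_norm: float | None = None):
        super().__init__(message)
        self.residual_norm = residual_norm


class BackendError(VcssError):
    """One or more docking-backend calls failed during a screening run."""

    def __init__(self, message: str, failures: list | None = None):
        super().__init__(message)
        self.failures = failures or []
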