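"""Exception hierarchy for the cascade contouring pipeline."""


class CascadeError(Exception):
    """Base class for all package errors."""


class FormatError(CascadeError):
    """Unreadable or structurally invalid image file."""


class StateError(CascadeError):
    """Operation applied to an object in the wrong state (e.g. double preprocessing)."""


class ContractError(CascadeError):
    """Caller violated an interface contract (shape mismatch, invalid argument)."""


class DataError(CascadeError):
    """Training/evaluation data insufficient or inconsistent."""


class SpecError(CascadeError):
    """Invalid phantom or corruption specification."""


class EmptyExtentError(CascadeError):
    """No slice exceeded the presence threshold; caller decides the fallback."""


class EmptyMaskError(CascadeError):
    """An operation requiring a non-empty mask received an empty one."""


class NoBifurcationError(CascadeError):
    """The vessel mask never splits into two components."""


class VesselQualityError(CascadeError):
    """Vessel mask too fragmented for reliable bifurcation detection."""


class DegenerateBorderError(CascadeError):
    """A border rule anchored at slice 0 cannot be applied."""


class DependencyError(CascadeError):
    """A pipeline stage is missing a required upstream model or artifact."""


class CurationError(CascadeError):
    """Cross-training failed during label curation."""


class UndefinedMetricError(CascadeError):
    """Surface distances are undefined for empty masks; reported as missing."""
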