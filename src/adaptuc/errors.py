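"""Exception hierarchy shared across the package."""


class AdaptUCError(Exception):
    """Base class for all package-specific errors."""


class ModelFormatError(AdaptUCError):
    """A model file could not be parsed in the declared dialect."""


class ModelError(AdaptUCError):
    """A parsed model violates a structural requirement (e.g. no biomass)."""


class AugmentationError(AdaptUCError):
    """Pathway insertion failed (typically an id collision)."""


class ConfigurationError(AdaptUCError):
    """A user-supplied identifier or setting is invalid for this model."""


class SolverError(AdaptUCError):
    """The LP/MILP backend failed; carries the backend status."""

    def __init__(self, message: str, status=None):
        super().__init__(message)
        self.status = status


class SizeError(AdaptUCError):
    """An enumeration guard was exceeded."""
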