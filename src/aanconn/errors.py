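"""Exception hierarchy shared across the pipeline."""


class AanconnError(Exception):
    """Base class for all package errors."""


class ValidationError(AanconnError):
    """Input data violates a schema invariant (e.g. connecting > launched)."""


class ConfigError(AanconnError):
    """A threshold, band definition, or mode is outside its valid range."""


class EmptyRoiError(AanconnError):
    """A label id was requested that has no voxels in the label volume."""


class IncompleteGeometryError(AanconnError):
    """A barycenter is missing for an ROI referenced by a downstream step."""
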