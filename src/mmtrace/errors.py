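"""Exception hierarchy for the mother-machine analysis pipeline."""


class MMTraceError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(MMTraceError):
    """Missing or inconsistent configuration (e.g. no pixel size available)."""


class DegenerateInputError(MMTraceError):
    """Input carries no usable signal (constant image, flat profile, ...)."""


class StructureNotFoundError(MMTraceError):
    """No mother-machine channel array could be located in a frame."""


class GeometryError(MMTraceError):
    """Channel geometry estimation produced an implausible result."""


class EstimationFailedError(MMTraceError):
    """A statistical estimate (e.g. rotation angle) could not be formed."""
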