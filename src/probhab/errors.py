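"""Exception hierarchy used across the package."""


class ProbHabError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ProbHabError):
    """A required attribute column is missing or an attribute violates its invariant."""


class CRSError(ProbHabError):
    """Coordinates are geographic (degree units) and no working projection was configured,
    or inputs mix coordinate systems."""


class GeometryError(ProbHabError):
    """Empty or invalid geometry where a valid polygon is required."""


class ParameterError(ProbHabError, ValueError):
    """A parameter is outside its documented domain."""


class ConfigError(ProbHabError):
    """A rubric evidence config references an unknown topic key."""


class AlignmentError(ProbHabError):
    """Grids that must share a common georeference do not."""


class UndefinedRateError(ProbHabError):
    """A capture rate was requested for an empty evaluation set."""


class ProductNotPossibleError(ProbHabError):
    """No model passed the exclusion gates and calibration, so no
    probable-habitat product can be built for the species."""
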