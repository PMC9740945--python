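"""Exception hierarchy for regmap."""


class RegmapError(Exception):
    """Base class for all regmap errors."""


class FormatError(RegmapError):
    """A file or string does not conform to the expected format."""


class CoordinateError(RegmapError):
    """Coordinates violate an invariant (start >= end, outside chromosome, ...)."""


class AnnotationError(RegmapError):
    """Gene annotation is missing required information or is inconsistent."""


class DegenerateInputError(RegmapError):
    """An operation received an input on which its result is undefined
    (empty group after a cutoff, zero-size universe, empty region set, ...)."""


class PlacementError(RegmapError):
    """A random placement could not be satisfied within its constraints."""


class ConfigError(RegmapError):
    """A simulation configuration is infeasible or inconsistent."""
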