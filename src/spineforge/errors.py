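"""Exception hierarchy shared across the package."""


class SpineforgeError(Exception):
    """Base class for all package errors."""


class InvalidLabelError(SpineforgeError):
    """A vertebral label outside the supported T1..L5 range {8..24}."""


class GeometryError(SpineforgeError):
    """A phantom or projection geometry that cannot be realized."""


class MissingTemplateError(SpineforgeError):
    """Atlas lookup for a label with no template."""


class MissingLabelError(SpineforgeError):
    """A label absent from a label volume."""


class DegenerateImageError(SpineforgeError):
    """An image whose statistics make an operation undefined (e.g. sigma=0)."""


class OutOfBoundsError(SpineforgeError):
    """A coordinate outside the image bounds."""


class BatchContractError(SpineforgeError):
    """A vertebra batch violating the one-spine, ascending-label contract."""


class DataError(SpineforgeError):
    """Malformed or inconsistent dataset contents."""


class DivergenceError(SpineforgeError):
    """Training produced a non-finite loss."""


class ConfigError(SpineforgeError):
    """Invalid or unknown configuration values."""


class MetricError(SpineforgeError):
    """A metric undefined for the given inputs (e.g. empty masks)."""


class ParameterError(SpineforgeError):
    """A metric/spectrum parameter outside its valid range."""
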