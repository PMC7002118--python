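"""Exception hierarchy for the gfscell pipeline."""


class GfsError(Exception):
    """Base class for all gfscell errors."""


class InvalidParameterError(GfsError, ValueError):
    """A shape or configuration parameter is out of its valid range."""


class DegenerateShapeError(GfsError, ValueError):
    """A polygon is degenerate (collinear or repeated vertices)."""


class PlacementError(GfsError, RuntimeError):
    """A scene could not accommodate the requested instances."""


class OutOfBoundsError(GfsError, ValueError):
    """A keypoint falls outside the image frame."""


class InvalidInputError(GfsError, ValueError):
    """An array or record violates an operation's precondition."""


class ConfigurationError(GfsError, ValueError):
    """Inconsistent run configuration (e.g. verification without a reference)."""


class ValidationError(GfsError, ValueError):
    """A serialized record violates its schema; carries the offending fields."""

    def __init__(self, message: str, fields: list[str] | None = None):
        super().__init__(message)
        self.fields = fields or []
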