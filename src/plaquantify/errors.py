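"""Exception hierarchy shared across the package."""


class PlaquantifyError(Exception):
    """Base class for all package errors."""


class FormatError(PlaquantifyError, ValueError):
    """An input file or array does not match the expected format
    (non-8-bit, non-RGB, malformed ROI record, ...)."""


class GeometryError(PlaquantifyError, ValueError):
    """A region of interest is geometrically invalid or incompatible with
    the image it is bound to (self-intersecting polygon, empty mask,
    out-of-bounds ROI, non-positive semi-axis, ...)."""


class DataError(PlaquantifyError, ValueError):
    """Subject or measurement data violate a contract (duplicate visit,
    one-class outcome, zero marginal in a contingency table, ...)."""


class ParameterError(PlaquantifyError, ValueError):
    """A tuning parameter lies outside its documented range."""


class ConfigError(PlaquantifyError, ValueError):
    """A simulation or pipeline configuration is infeasible."""


class DegenerateReferenceError(PlaquantifyError, ValueError):
    """The plaque-free reference region carries no usable green signal."""


class SeparationError(PlaquantifyError, RuntimeError):
    """Logistic fit failed to converge because a predictor perfectly
    separates the outcome classes."""

    def __init__(self, message: str, predictor: str | None = None):
        super().__init__(message)
        self.predictor = predictor
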