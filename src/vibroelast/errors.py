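"""Exception hierarchy shared across the package."""


class VibroelastError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(VibroelastError, ValueError):
    """A physical or configuration parameter is outside its valid domain."""


class GeometryError(VibroelastError, ValueError):
    """Source/grid/patch geometry is inconsistent (source inside footprint,
    margin too large, field smaller than a patch, ...)."""


class FormatError(VibroelastError, ValueError):
    """A scan-export file violates the documented text dialect."""


class EmptyInputError(FormatError):
    """A scan-export file contains no data rows."""


class InterpolationError(VibroelastError, ValueError):
    """Scattered points cannot support the requested interpolation
    (degenerate geometry or grid points outside the convex hull)."""


class LabelError(VibroelastError, ValueError):
    """A class value or label index is outside the configured class set."""


class ConfigError(VibroelastError, ValueError):
    """An experiment/run configuration is internally inconsistent."""


class ProtocolError(VibroelastError, RuntimeError):
    """A training-protocol contract was violated (augmenting the test split,
    fine-tuning with an unfrozen conv block, evaluating a missing model, ...)."""


class UndefinedMetricError(VibroelastError, ValueError):
    """A metric is undefined for the given ground truth (e.g. one-vs-rest AUC
    with no positive or no negative samples for a class)."""
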