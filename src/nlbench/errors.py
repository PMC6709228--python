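"""Exception hierarchy shared across the package."""


class ConfigurationError(ValueError):
    """A parameter or sweep configuration is invalid."""


class MontageFormatError(ValueError):
    """A sensor-montage file or layout is malformed."""


class GeometryError(ValueError):
    """A source or sensor lies outside the head-model geometry."""


class ShapeError(ValueError):
    """Array dimensions do not match the operation's contract."""


class NumericalError(RuntimeError):
    """An iterative or series computation failed to converge."""


class EstimationError(RuntimeError):
    """Not enough data to estimate a second-order statistic."""


class DegenerateDataError(RuntimeError):
    """Input is degenerate for the requested quantity (e.g. all-zero signal)."""


class EvaluationError(RuntimeError):
    """A metric is undefined for the given inputs (e.g. empty voxel set)."""
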