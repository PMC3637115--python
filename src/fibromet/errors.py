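"""Exception hierarchy shared across the pipeline."""


class FibrometError(Exception):
    """Base class for all package errors."""


class ParameterError(FibrometError, ValueError):
    """An argument violates a documented precondition."""


class ResolutionError(FibrometError, ValueError):
    """A requested shape cannot be rendered at the given pixel size."""


class OverlapError(FibrometError, ValueError):
    """Two synthetic object footprints intersect; objects must be discrete."""


class DegenerateHistogramError(FibrometError, ValueError):
    """Automatic thresholding needs at least two distinct intensity levels."""


class DegenerateShapeError(FibrometError, ValueError):
    """A boundary is collinear or otherwise has no 2-D extent."""


class FormatError(FibrometError, ValueError):
    """An image file is unsupported or truncated."""


class ConfigError(FibrometError, ValueError):
    """A pipeline configuration value is missing or invalid."""


class PipelineError(FibrometError, RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
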