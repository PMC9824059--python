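"""Exception types used across the package."""


class GaitSurfaceError(Exception):
    """Base class for package errors."""


class InvalidConfigError(GaitSurfaceError, ValueError):
    """A configuration violates its invariants."""


class NoGaitDetectedError(GaitSurfaceError, RuntimeError):
    """No periodic gait structure could be found in a signal."""


class FeatureExtractionError(GaitSurfaceError, ValueError):
    """A stride segment cannot yield the full feature set."""


class UndefinedMetricError(GaitSurfaceError, ValueError):
    """A metric is undefined for the given inputs (e.g. one-class AUC)."""


class SchemaError(GaitSurfaceError, ValueError):
    """A file does not match the documented on-disk schema."""
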