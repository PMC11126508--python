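"""Exception hierarchy for growthmsm."""


class GrowthMsmError(Exception):
    """Base class for all growthmsm errors."""


class FormatError(GrowthMsmError):
    """A file or table does not satisfy the expected schema or invariants."""


class OutOfRangeError(GrowthMsmError):
    """A query age falls outside the growth-reference table."""


class InvalidMeasurementError(GrowthMsmError):
    """A measurement (BMI, z-score) is non-finite or non-positive."""


class StructureError(GrowthMsmError):
    """An intensity matrix violates the allowed transition structure."""


class ConfigurationError(GrowthMsmError):
    """A simulation or pipeline configuration is inconsistent."""


class DesignError(GrowthMsmError):
    """A survey design violates a requirement (e.g. singleton-cluster stratum)."""


class EstimationError(GrowthMsmError):
    """Model estimation cannot proceed (e.g. empty panel)."""


class NotConvergedError(EstimationError):
    """A downstream quantity was requested from a non-converged fit."""


class InferenceError(GrowthMsmError):
    """Replicate-based variance estimation failed (too many bad replicates)."""


class ScheduleError(GrowthMsmError):
    """A matrix schedule has gaps, overlaps or non-stochastic entries."""


class ExtractionError(GrowthMsmError):
    """A dataset-extraction rule produced an unusable dataset."""
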