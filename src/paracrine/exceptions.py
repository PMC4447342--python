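"""Exception hierarchy for the paracrine pipeline.

All package-specific errors derive from :class:`ParacrineError` so callers can
catch the whole family with one clause; the subclasses distinguish parameter
misuse from data problems and numerical degeneracies.
"""


class ParacrineError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ParacrineError, ValueError):
    """A configuration or function parameter is outside its documented domain."""


class DomainError(ParacrineError, ValueError):
    """A numeric input (probability, rate, correlation) is outside its domain."""


class ConsistencyError(ParacrineError, ValueError):
    """Two inputs that must agree (gene sets, pairing keys) do not."""


class PairingError(ConsistencyError):
    """Paired stromal/tumor samples cannot be matched."""


class InsufficientReplicationError(ParacrineError, ValueError):
    """Fewer than two replicates in a group of a differential test."""


class InsufficientSampleError(ParacrineError, ValueError):
    """Too few samples for a conditional-independence test of this size."""


class DegenerateGeneError(ParacrineError, ValueError):
    """A gene has zero variance where standardization is required."""


class NumericalRankError(ParacrineError, ValueError):
    """A matrix is singular beyond the tolerated threshold."""


class RankDeficiencyError(ParacrineError, ValueError):
    """A regression design matrix is collinear."""


class SizeError(ParacrineError, ValueError):
    """An exhaustive enumeration would exceed its configured cap."""


class CalibrationError(ParacrineError, ValueError):
    """The known-positive anchor of a calibration run is unavailable."""


class PipelineStageError(ParacrineError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class ParseError(ParacrineError, ValueError):
    """A file could not be parsed; message includes the offending location."""
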