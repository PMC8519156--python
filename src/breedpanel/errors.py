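"""Exception hierarchy used across the package."""


class BreedPanelError(Exception):
    """Base class for all package errors."""


class FormatError(BreedPanelError):
    """Malformed or inconsistent input file."""


class LabelingError(BreedPanelError):
    """Sample-label table inconsistent with the genotype data."""


class EmptyResultError(BreedPanelError):
    """A filter removed every marker or sample."""


class ComputationError(BreedPanelError):
    """A statistic is undefined on the given input."""


class GroupLookupError(BreedPanelError):
    """A requested population group does not exist."""


class ScheduleShortfallError(BreedPanelError):
    """A pruning step could not reach its requested marker count."""

    def __init__(self, step_index: int, requested: int, achieved: int, distance_mb: float):
        self.step_index = step_index
        self.requested = requested
        self.achieved = achieved
        self.distance_mb = distance_mb
        super().__init__(
            f"pruning step {step_index} (distance {distance_mb} Mb) selected "
            f"{achieved} of the requested {requested} markers"
        )


class CombineError(BreedPanelError):
    """Not enough unique markers to build a combined panel."""


class CalibrationError(BreedPanelError):
    """Drift calibration failed to reach its differentiation targets."""


class ConfigError(BreedPanelError):
    """Invalid pipeline configuration."""
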