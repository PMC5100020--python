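"""Exception hierarchy for the S-phase duration pipeline.

Every stage raises a subclass of :class:`SPhaseError` so that the pipeline
driver can attribute failures to a stage.
"""


class SPhaseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SPhaseError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ChannelResolutionError(SPhaseError, KeyError):
    """A required cytometry channel could not be resolved by name."""

    def __init__(self, missing, available):
        self.missing = missing
        self.available = list(available)
        super().__init__(
            f"channel {missing!r} not found; available channels: {self.available}"
        )


class FormatError(SPhaseError, ValueError):
    """Malformed event file (CSV or FCS)."""


class ManifestError(SPhaseError, ValueError):
    """Invalid time-course manifest."""


class GatingError(SPhaseError, RuntimeError):
    """Automatic gate placement failed (missing peaks, bad 4C/2C ratio)."""


class StatisticsError(SPhaseError, RuntimeError):
    """A required gated population is empty."""


class DegeneratePopulationError(SPhaseError, ZeroDivisionError):
    """G2/M mean does not exceed the G1 mean; RM is undefined."""


class RankDeficiencyError(SPhaseError, ValueError):
    """Design matrix is rank deficient (e.g. all observation times equal)."""


class FittingInsufficiencyError(SPhaseError, ValueError):
    """Too few points (or too few distinct times) for the requested fit."""


class NoProgressionError(SPhaseError, ValueError):
    """First-segment slope is not positive; the labeled cohort is not advancing."""
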