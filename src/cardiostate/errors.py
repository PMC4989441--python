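"""Exception hierarchy shared across the analysis stages."""


class CardiostateError(Exception):
    """Base class for all package-specific errors."""


class NonFiniteSignal(CardiostateError):
    """Input samples contain NaN or infinity."""


class NoEventsDetected(CardiostateError):
    """Event detector found no events (e.g. flat signal)."""


class TooFewEvents(CardiostateError):
    """An operation needs more marker events than were supplied."""


class NoMatches(CardiostateError):
    """No pulse foot could be paired with a preceding R-peak."""


class NyquistViolation(CardiostateError):
    """Requested analysis frequency exceeds fs/2."""


class DurationTooShort(CardiostateError):
    """Record too short to resolve the requested frequency."""


class EmptyInterval(CardiostateError):
    """A frequency interval contains no grid frequency."""


class GridMismatch(CardiostateError):
    """Two wavelet transforms do not share frequency/time grids."""


class EmptyCOI(CardiostateError):
    """No sample lies inside the cone of influence."""


class TooFewSurrogates(CardiostateError):
    """Surrogate count insufficient for the requested significance level."""


class RecordTooShort(CardiostateError):
    """Record shorter than twice the minimum surrogate time shift."""


class GroupTooSmall(CardiostateError):
    """A group comparison needs more subjects per group."""


class LengthMismatch(CardiostateError):
    """Paired samples differ in length."""


class AllZeroDifferences(CardiostateError):
    """Paired test undefined: every difference is zero."""


class WindowTooShort(CardiostateError):
    """Synchronisation-index window shorter than two mean periods."""


class MissingAnalysis(CardiostateError):
    """A feature vector attribute has no backing analysis result."""


class DimensionMismatch(CardiostateError):
    """Distance metric dimension does not match the feature vectors."""


class ClassTooSmall(CardiostateError):
    """Too few subjects in a class for metric learning / evaluation."""


class EmptyTrainingSet(CardiostateError):
    """Nearest-neighbour classification requires a non-empty training set."""


class ConfigError(CardiostateError):
    """Invalid or incomplete pipeline configuration."""
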