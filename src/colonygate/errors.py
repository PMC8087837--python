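"""Exception types raised across the pipeline."""


class ColonyGateError(Exception):
    """Base class for all package errors."""


class NoParticleError(ColonyGateError):
    """Segmentation found no foreground pixel at the configured threshold."""


class UndefinedRatioError(ColonyGateError):
    """A channel-mean ratio has a zero denominator."""


class FrameOverflowError(ColonyGateError):
    """A rendered particle does not fit inside the frame; enlarge the frame."""


class DuplicateClassError(ColonyGateError):
    """Two generation profiles share the same class name."""


class InsufficientClassError(ColonyGateError):
    """A class has fewer particles than the requested training-subset size."""


class UnknownFeatureError(ColonyGateError):
    """A gate references a feature name that is not a particle property."""


class MissingFeatureError(ColonyGateError):
    """A dataset lacks a feature column required by a filter or reader."""


class EmptyIntersectionError(ColonyGateError):
    """Two gates on the same feature do not overlap (min > max)."""


class ClassMismatchError(ColonyGateError):
    """Filters for different classes were combined."""


class DegenerateClassError(ColonyGateError):
    """A metric needs both positives and negatives for the class."""
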