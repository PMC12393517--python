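"""Exception hierarchy shared across the package."""


class MinicircError(Exception):
    """Base class for all package-specific errors."""


class StructuralInputError(MinicircError):
    """A reference structure is too small or malformed for parameter derivation."""


class LabelingError(StructuralInputError):
    """An expected atom class (site/strand combination) is missing."""


class SequenceError(MinicircError):
    """A base string contains characters outside the DNA alphabet."""


class GeometryError(MinicircError):
    """A coordinate transform is undefined for the given geometry."""


class TopologyError(MinicircError):
    """Bonded-topology construction was asked to do something inconsistent."""


class FrameError(MinicircError):
    """A reference frame could not be constructed (degenerate geometry)."""


class UndefinedAngleError(MinicircError):
    """An angular quantity is undefined (zero-length vector or zero resultant)."""


class UndefinedStatisticError(MinicircError):
    """A summary statistic is undefined for the given inputs."""


class SegmentationError(MinicircError):
    """Image analysis failed (singular background fit, empty mask, zero mass)."""


class FitError(MinicircError):
    """A least-squares fit is underdetermined or rank deficient."""


class ComparabilityError(MinicircError):
    """Two results cannot be compared (e.g. different fit periods)."""


class ConfigError(MinicircError):
    """A run configuration is invalid (unknown keys, missing fields)."""


class TrajectoryError(MinicircError):
    """A trajectory file is corrupt or inconsistent between frames."""


class PlacementError(MinicircError):
    """Synthetic scene generation could not place particles without overlap."""
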