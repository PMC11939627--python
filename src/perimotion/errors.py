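"""Exception hierarchy for the perimotion pipeline.

Every stage raises a distinct subclass of :class:`PerimotionError` so the CLI
can map error classes to exit codes and report which stage failed.
"""


class PerimotionError(Exception):
    """Base class for all perimotion errors."""

    exit_code = 1


class GridIncompatibilityError(PerimotionError):
    """Volumes/masks of one study do not share grid shape and affine."""

    exit_code = 2


class IncompleteSeriesError(PerimotionError):
    """A phase series does not contain exactly the nine 10-90% phases."""

    exit_code = 3


class DegenerateCenterlineError(PerimotionError):
    """A centerline with fewer than two points."""

    exit_code = 4


class EmptyRegionError(PerimotionError):
    """A mask or point set that must be nonempty is empty."""

    exit_code = 5


class RegistrationQualityError(PerimotionError):
    """Backend failure or a folded (non-diffeomorphic) displacement field."""

    exit_code = 6


class PairingError(PerimotionError):
    """Displacements and correspondences refer to mismatched point sets."""

    exit_code = 7


class EmptyDisparityError(PerimotionError):
    """Normalization requested with no pair-phase samples."""

    exit_code = 8


class EmptyHistogramError(PerimotionError):
    """Histogram requested over an empty sample set."""

    exit_code = 9


class InsufficientSamplesError(PerimotionError):
    """A phase carries no samples for the KS matrix."""

    exit_code = 10


class PhantomSpecError(PerimotionError):
    """A geometrically impossible or invalid phantom specification."""

    exit_code = 11
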