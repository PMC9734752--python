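"""Exception types shared across the package."""


class MirrorGameError(Exception):
    """Base class for all package-specific errors."""


class EstimationError(MirrorGameError):
    """Raised when model parameters cannot be estimated from a trajectory."""


class DegenerateTestError(MirrorGameError):
    """Raised when a statistical test is undefined for the given data
    (e.g. a signed-rank test on all-zero differences)."""


class TrajectoryFormatError(MirrorGameError):
    """Raised on malformed trajectory / button / questionnaire files."""


class GridMismatchError(MirrorGameError):
    """Raised when two time series do not share the same sampling grid."""
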