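"""Exception hierarchy for ki67calib."""


class Ki67CalibError(Exception):
    """Base class for all package-specific errors."""


class PlacementInfeasibleError(Ki67CalibError):
    """Requested cell density cannot be realized under the overlap constraint."""


class UndefinedLIError(Ki67CalibError):
    """A labelling index was requested but no tumour cell profiles are available.

    Carries the sampling geometry (``n_frames``, ``m_segments``) when raised
    from a grid count so callers can still report the sampling state.
    """

    def __init__(self, message: str, n_frames: int | None = None,
                 m_segments: int | None = None):
        super().__init__(message)
        self.n_frames = n_frames
        self.m_segments = m_segments


class InvalidGridError(Ki67CalibError):
    """Counting-frame grid parameters are geometrically impossible."""


class UndefinedSegmentsError(Ki67CalibError):
    """External-segment count requested for an empty frame set."""


class EmptyTumourError(Ki67CalibError):
    """Tumour segmentation produced an empty mask."""


class ConfigError(Ki67CalibError):
    """Invalid analysis configuration value."""


class DegenerateFitError(Ki67CalibError):
    """Regression input is degenerate (constant explanatory variable)."""


class AmbiguousAxisError(Ki67CalibError):
    """Principal axis of an (almost) isotropic point cloud is not identifiable."""


class InsufficientDataError(Ki67CalibError):
    """Not enough observations for the requested statistic."""


class RankDeficiencyError(Ki67CalibError):
    """Design matrix is rank deficient (collinear predictors)."""


class AlignmentError(Ki67CalibError):
    """Result lists to be compared do not refer to the same spots."""


class CalibrationFailedError(Ki67CalibError):
    """No candidate in the calibration search space produced a usable result."""
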