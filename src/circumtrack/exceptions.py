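"""Exception hierarchy for the tracking pipeline."""


class CircumtrackError(Exception):
    """Base class for all package errors."""


class PointBehindCamera(CircumtrackError):
    """A 3D point has non-positive depth in the camera frame."""


class DistortionDivergence(CircumtrackError):
    """Fixed-point undistortion failed to converge."""

    def __init__(self, residual: float):
        self.residual = residual
        super().__init__(f"undistortion did not converge (residual {residual:.3e})")


class UnderConstrainedCalibration(CircumtrackError):
    """Too few or degenerate board views for calibration."""


class UnstableStereoCalibration(CircumtrackError):
    """Per-pair relative poses disagree beyond tolerance."""


class DegenerateRig(CircumtrackError):
    """Zero baseline or otherwise unusable stereo geometry."""


class IncompatibleFrame(CircumtrackError):
    """Frame dimensions do not match the background model."""


class EpipoleCoincidence(CircumtrackError):
    """Epipolar line is degenerate (point maps to the epipole)."""


class Unsynchronizable(CircumtrackError):
    """No photoperiod transition found in a luminance series."""


class NothingToInterpolate(CircumtrackError):
    """A track contains no observed frames."""


class InvalidCorrection(CircumtrackError):
    """A manual correction references a frame outside the track range."""


class IllConditionedTriangulation(CircumtrackError):
    """Viewing rays are near-parallel; triangulation unreliable."""


class EmptyReconstruction(CircumtrackError):
    """No aligned frame pairs available for reconstruction."""


class OutOfFrame(CircumtrackError):
    """The simulated tip projects outside both camera views."""
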