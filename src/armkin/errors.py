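"""Exception hierarchy for the kinematics toolkit.

All errors raised by armkin derive from :class:`ArmKinError` so callers can
catch the whole family.  The distinction between :class:`UnreachableTargetError`
(the geometry cannot close the kinematic chain at all) and
:class:`AnatomicalViolationError` (the chain closes, but only in a posture a
human shoulder cannot adopt) matters in the streaming pipeline, where the
latter is downgraded to a flagged sample instead of aborting a recording.
"""


class ArmKinError(Exception):
    """Base class for all armkin errors."""


class InvalidInputError(ArmKinError, ValueError):
    """Malformed or non-finite input data."""


class UnreachableTargetError(ArmKinError):
    """The end-effector target violates the chain's triangle inequality."""


class AnatomicalViolationError(ArmKinError):
    """Both algebraic shoulder solutions breach the anatomical sign rules.

    Corresponds to the "shoulder dislocation" condition: the shoulder centre
    would sit below the horizontal plane through the sternoclavicular origin
    (Zc <= 0) or medial to it (Xc <= 0).
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SingularConfigurationError(ArmKinError):
    """A joint angle is undefined at this configuration (e.g. atan2(0, 0))."""


class DegenerateConfigurationError(ArmKinError):
    """The elimination pivots of the plane construction are all ill-conditioned."""


class InconsistentPoseError(ArmKinError):
    """No branch candidate reproduces the measured pose within tolerance."""


class TrajectoryQualityError(ArmKinError):
    """Too many frames of a recording were flagged to trust the trajectory."""


class ConfigError(ArmKinError, ValueError):
    """Invalid or unknown configuration key/value."""
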