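"""Marker-coordinate geometry: camera pitch extraction and AP projection.

A ceiling-mounted optical tracker reports each rigid marker as a 4x4
homogeneous transform in the camera's global frame.  Because the camera
looks down at an angle, the patient's anterior-posterior (AP) breathing
motion is mixed into the global x and z axes.  A single y-axis pitch
rotation by the camera angle theta separates the components:

    [ cos(theta)  0  sin(theta) ]   [x_global]   [x_anterior/posterior]
    [     0       1      0      ] . [y_global] = [y_medial/lateral    ]
    [-sin(theta)  0  cos(theta) ]   [z_global]   [z_cranial/caudal    ]

theta is read from the marker orientation matrix as arcsin(-R31).  The
AP components of the patient marker and of a second marker mounted on
the CT table are then subtracted sample-wise, removing table feed and
load-dependent table sag from the breathing signal.

Conventions: anterior displacement is positive, table sag is negative;
units are millimetres and seconds throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidRotationError, ValidationError

__all__ = [
    "Pose",
    "ApSample",
    "ORTHONORMALITY_TOL",
    "pitch_matrix",
    "extract_pitch",
    "rotate_to_patient",
    "project_ap",
    "correct_breathing",
    "compose_pose",
    "estimate_session_pitch",
]

#: Tolerance on R^T R = I and det(R) = 1 for incoming poses.  Poses beyond
#: it are rejected, not re-orthogonalised.
ORTHONORMALITY_TOL = 1e-6


def _check_rotation(R: np.ndarray, tol: float = ORTHONORMALITY_TOL) -> None:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidRotationError(f"rotation must be 3x3, got {R.shape}")
    if not np.all(np.isfinite(R)):
        raise InvalidRotationError("rotation matrix contains non-finite values")
    err = np.max(np.abs(R.T @ R - np.eye(3)))
    if err > tol:
        raise InvalidRotationError(
            f"rotation not orthonormal: max |R^T R - I| = {err:.3g} > {tol:g}"
        )
    det = np.linalg.det(R)
    if abs(det - 1.0) > tol:
        raise InvalidRotationError(f"det(R) = {det:.9f}, expected +1")


@dataclass(frozen=True)
class Pose:
    """Time-stamped rigid-marker pose.

    Parameters
    ----------
    t : float
        Acquisition time in seconds.
    marker_id : str
        ``"patient"`` or ``"table"``.
    M : (4, 4) ndarray
        Homogeneous transform; rotation sub-matrix must be a proper
        rotation to within :data:`ORTHONORMALITY_TOL`, translation in mm.
    """

    t: float
    marker_id: str
    M: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        if M.shape != (4, 4):
            raise ValidationError(f"pose matrix must be 4x4, got {M.shape}")
        object.__setattr__(self, "M", M)
        _check_rotation(M[:3, :3])
        if not np.all(np.isfinite(M[:3, 3])):
            raise ValidationError("pose translation contains non-finite values")

    @property
    def R(self) -> np.ndarray:
        """Rotation sub-matrix (marker orientation)."""
        return self.M[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """Global-frame translation (x, y, z) in mm."""
        return self.M[:3, 3]


@dataclass(frozen=True)
class ApSample:
    """One corrected AP sample: patient and table projections plus difference."""

    t: float
    x_breathing: float
    x_table: float
    x_corrected: float

    def __post_init__(self) -> None:
        if self.x_corrected != self.x_breathing - self.x_table:
            raise ValidationError(
                "x_corrected must equal x_breathing - x_table exactly"
            )

    @classmethod
    def make(cls, t: float, x_breathing: float, x_table: float) -> "ApSample":
        return cls(t, x_breathing, x_table, x_breathing - x_table)


def pitch_matrix(theta: float) -> np.ndarray:
    """Y-axis pitch rotation mapping global to patient coordinates."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def extract_pitch(pose: Pose | np.ndarray) -> float:
    """Pitch angle theta = arcsin(-R31) from a marker orientation matrix.

    ``R31`` is the (3, 1) element of the rotation sub-matrix.  The
    principal arcsin branch is used, so theta is in [-pi/2, pi/2].

    Raises
    ------
    InvalidRotationError
        If the rotation is not orthonormal within tolerance or |R31|
        exceeds 1 beyond rounding error.
    """
    R = pose.R if isinstance(pose, Pose) else np.asarray(pose, dtype=float)
    _check_rotation(R)
    r31 = R[2, 0]
    if abs(r31) > 1.0 + 1e-9:
        raise InvalidRotationError(f"|R31| = {abs(r31):.12f} > 1")
    return float(np.arcsin(np.clip(-r31, -1.0, 1.0)))


def rotate_to_patient(v_global: np.ndarray, theta: float) -> np.ndarray:
    """Rotate global coordinates into the patient frame (AP, ML, CC).

    Accepts a single 3-vector or an (..., 3) array; norm is preserved.
    """
    v = np.asarray(v_global, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite input vector")
    return v @ pitch_matrix(theta).T


def project_ap(v_global: np.ndarray, theta: float) -> float | np.ndarray:
    """Anterior-posterior component: x_global*cos(theta) + z_global*sin(theta).

    Identical to the first component of :func:`rotate_to_patient`;
    vectorised over leading axes of an (..., 3) input.
    """
    v = np.asarray(v_global, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite input vector")
    out = v[..., 0] * np.cos(theta) + v[..., 2] * np.sin(theta)
    return float(out) if out.ndim == 0 else out


def correct_breathing(x_breathing, x_table):
    """Table-motion-corrected breathing signal: exact sample-wise subtraction."""
    xb = np.asarray(x_breathing, dtype=float)
    xt = np.asarray(x_table, dtype=float)
    if not (np.all(np.isfinite(xb)) and np.all(np.isfinite(xt))):
        raise ValidationError("non-finite amplitude input")
    out = xb - xt
    return float(out) if out.ndim == 0 else out


def compose_pose(
    theta: float,
    translation,
    t: float = 0.0,
    marker_id: str = "patient",
) -> Pose:
    """Build a pose whose orientation encodes camera pitch ``theta``.

    The stored rotation is the y-axis pitch matrix, whose (3, 1) element
    is -sin(theta), so ``extract_pitch(compose_pose(theta, v)) == theta``
    for |theta| < pi/2.  The translation is stored verbatim.
    """
    if not abs(theta) < np.pi / 2:
        raise ValidationError(f"|theta| must be < pi/2, got {theta}")
    M = np.eye(4)
    M[:3, :3] = pitch_matrix(theta)
    M[:3, 3] = np.asarray(translation, dtype=float)
    return Pose(t=t, marker_id=marker_id, M=M)


def estimate_session_pitch(poses, window_s: float = 1.0) -> float:
    """Session camera pitch: median of per-frame pitch over an initial window.

    The camera angle is fixed for a session, so a single robust estimate
    from the table marker's first ``window_s`` seconds avoids injecting
    per-frame orientation noise into the position correction.

    Parameters
    ----------
    poses : sequence of Pose or PoseStream
        Frames ordered in time; typically the table-marker stream.
    window_s : float
        Length of the initial window, seconds.
    """
    # PoseStream quacks via .poses(); plain iterables of Pose also work
    frames = list(poses.poses()) if hasattr(poses, "poses") else list(poses)
    if not frames:
        raise ValidationError("cannot estimate pitch from an empty pose stream")
    t0 = frames[0].t
    thetas = [extract_pitch(p) for p in frames if p.t <= t0 + window_s]
    return float(np.median(thetas))
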