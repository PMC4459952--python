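"""Rigid-body geometry primitives.

Rotations are stored as unit quaternions ``(w, x, y, z)``; axis-angle input is
accepted at the API boundary (the convention used for rigid-body docking
moves).  All angles are degrees externally and radians internally.  The
quaternion algebra is written out explicitly because it sits in the sampler's
hot loop; it is cross-checked against :mod:`scipy.spatial.transform` in the
test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RigidTransform",
    "quat_from_axis_angle",
    "quat_multiply",
    "quat_conjugate",
    "quat_to_matrix",
    "quat_angle_deg",
    "random_unit_vector",
    "relative_transform",
    "superpose_kabsch",
    "apply_superposition",
]


def quat_from_axis_angle(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_deg`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    half = 0.5 * np.deg2rad(angle_deg)
    q = np.empty(4)
    q[0] = np.cos(half)
    q[1:] = (np.sin(half) / n) * axis
    return q


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a*b`` (apply ``b`` first, then ``a``)."""
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    return np.array([q[0], -q[1], -q[2], -q[3]])


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """3x3 proper rotation matrix of a unit quaternion."""
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quat_angle_deg(q: np.ndarray) -> float:
    """Rotation angle in [0, 180] degrees represented by a unit quaternion."""
    w = min(1.0, abs(float(q[0])))
    return float(np.rad2deg(2.0 * np.arccos(w)))


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform direction on the unit sphere (Gaussian normalization)."""
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


@dataclass
class RigidTransform:
    """Proper rigid motion: unit quaternion rotation plus translation (Å).

    How the rotation centre is chosen is up to the caller; a docking pose
    applies the rotation about the mobile partner's centroid so that the
    translation component directly measures centre displacement.
    """

    quat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.quat = np.asarray(self.quat, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        n = np.linalg.norm(self.quat)
        if abs(n - 1.0) > 1e-9:
            if n == 0.0:
                raise ValueError("zero quaternion")
            self.quat = self.quat / n

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(
        cls, axis: np.ndarray, angle_deg: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        return cls(quat_from_axis_angle(axis, angle_deg), np.asarray(translation, float))

    @property
    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.quat)

    def copy(self) -> "RigidTransform":
        new = object.__new__(RigidTransform)  # skip re-normalization
        new.quat = self.quat.copy()
        new.translation = self.translation.copy()
        return new


def relative_transform(
    current: RigidTransform, start: RigidTransform
) -> tuple[float, float]:
    """Translation norm (Å) and rotation angle (deg) of ``current`` vs ``start``.

    The angle is that of ``R_start^-1 · R_current``, in [0, 180] degrees; the
    translation is the Euclidean norm of the difference of the translation
    components.  Used for the 20 Å / 90° sampling-space restriction.
    """
    dt = float(np.linalg.norm(current.translation - start.translation))
    dq = quat_multiply(quat_conjugate(start.quat), current.quat)
    return dt, quat_angle_deg(dq)


def superpose_kabsch(
    mobile_coords: np.ndarray, target_coords: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns the proper rigid transform (``y = R x + t``, rotation about the
    origin) minimizing the RMSD, and the minimized RMSD in Å.  The Kabsch
    SVD solution with the determinant correction guarantees a rotation, never
    a reflection.

    Raises ``ValueError`` for fewer than 3 points, mismatched shapes, or
    degenerate (collinear) geometry.
    """
    mobile = np.asarray(mobile_coords, dtype=float)
    target = np.asarray(target_coords, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError("coordinate sets must have equal shape")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    h = (mobile - cm).T @ (target - ct)
    u, s, vt = np.linalg.svd(h)
    # Collinear sets leave the rotation about the line undetermined.
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) coordinate set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ct - rot @ cm
    diff = (mobile @ rot.T + t) - target
    rmsd = float(np.sqrt((diff * diff).sum() / mobile.shape[0]))
    return RigidTransform(_quat_from_matrix(rot), t), rmsd


def apply_superposition(coords: np.ndarray, transform: RigidTransform) -> np.ndarray:
    """Apply an origin-centred rigid transform ``y = R x + t``."""
    return np.asarray(coords, float) @ transform.matrix.T + transform.translation


def _quat_from_matrix(m: np.ndarray) -> np.ndarray:
    """Shepperd's method: stable rotation-matrix -> quaternion conversion."""
    tr = m[0, 0] + m[1, 1] + m[2, 2]
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        q = np.array(
            [0.25 * s, (m[2, 1] - m[1, 2]) / s, (m[0, 2] - m[2, 0]) / s, (m[1, 0] - m[0, 1]) / s]
        )
    elif m[0, 0] > m[1, 1] and m[0, 0] > m[2, 2]:
        s = np.sqrt(1.0 + m[0, 0] - m[1, 1] - m[2, 2]) * 2
        q = np.array(
            [(m[2, 1] - m[1, 2]) / s, 0.25 * s, (m[0, 1] + m[1, 0]) / s, (m[0, 2] + m[2, 0]) / s]
        )
    elif m[1, 1] > m[2, 2]:
        s = np.sqrt(1.0 + m[1, 1] - m[0, 0] - m[2, 2]) * 2
        q = np.array(
            [(m[0, 2] - m[2, 0]) / s, (m[0, 1] + m[1, 0]) / s, 0.25 * s, (m[1, 2] + m[2, 1]) / s]
        )
    else:
        s = np.sqrt(1.0 + m[2, 2] - m[0, 0] - m[1, 1]) * 2
        q = np.array(
            [(m[1, 0] - m[0, 1]) / s, (m[0, 2] + m[2, 0]) / s, (m[1, 2] + m[2, 1]) / s, 0.25 * s]
        )
    return q / np.linalg.norm(q)
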