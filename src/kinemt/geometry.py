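"""Angular statistics and rigid-pose helpers.

All angles are in degrees. The canonical angle interval is ``[-180, 180)``.
Poses follow the Relion particle convention: intrinsic ZYZ Euler angles
(rot, tilt, psi) plus in-plane origin shifts in Angstrom.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def wrap_deg(angle):
    """Wrap angle(s) into [-180, 180)."""
    return (np.asarray(angle, dtype=float) + 180.0) % 360.0 - 180.0


def circ_distance_deg(a, b):
    """Shortest angular distance |a - b| on the circle, in [0, 180]."""
    return np.abs(wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def circ_mean_deg(angles):
    """Unit-vector (circular) mean of angles in degrees, wrapped to [-180, 180).

    Undefined for a perfectly antipodal set; the numpy atan2 convention is
    used as the tie-break in that measure-zero case.
    """
    a = np.deg2rad(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("circ_mean_deg of empty set")
    s, c = np.sin(a).mean(), np.cos(a).mean()
    return float(wrap_deg(np.rad2deg(np.arctan2(s, c))))


def circ_median_deg(angles):
    """Circular median: the observed value minimizing the summed circular
    distance to all values. Ties resolve to the smallest wrapped angle."""
    a = wrap_deg(np.asarray(angles, dtype=float))
    if a.size == 0:
        raise ValueError("circ_median_deg of empty set")
    costs = circ_distance_deg(a[:, None], a[None, :]).sum(axis=1)
    best = costs.min()
    candidates = a[costs <= best + 1e-12]
    return float(candidates.min())


def euler_zyz_to_matrix(rot, tilt, psi):
    """Rotation matrix for intrinsic ZYZ Euler angles in degrees."""
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler_zyz(matrix):
    """Inverse of :func:`euler_zyz_to_matrix`; angles wrapped to [-180, 180)."""
    rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return tuple(float(x) for x in wrap_deg([rot, tilt, psi]))


def pose_to_matrix(rot, tilt, psi, shift=(0.0, 0.0, 0.0)):
    """4x4 homogeneous transform for an Euler pose plus translation (Å)."""
    T = np.eye(4)
    T[:3, :3] = euler_zyz_to_matrix(rot, tilt, psi)
    T[:3, 3] = np.asarray(shift, dtype=float)
    return T


def rot_z_matrix(angle_deg):
    """4x4 homogeneous rotation about the z (helical) axis."""
    T = np.eye(4)
    T[:3, :3] = Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()
    return T


def rotation_angle_axis(matrix):
    """Decompose a proper rotation matrix into (angle degrees in [0, 180],
    unit axis). The axis is ``None`` for angles indistinguishable from 0."""
    R = np.asarray(matrix, dtype=float)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_theta)))
    if angle < 1e-6:
        return angle, None
    if angle > 180.0 - 1e-6:
        # antiparallel case: axis from the symmetric part
        B = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(B), 0.0, None))
        k = int(np.argmax(axis))
        if axis[k] > 0:
            axis = B[:, k] / np.linalg.norm(B[:, k])
        return angle, axis
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    axis = v / np.linalg.norm(v)
    return angle, axis


def kabsch(mobile, reference):
    """Least-squares rigid superposition of two matched point sets.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` optimally matches
    ``reference``. ``det(R) = +1`` always (proper rotation).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("kabsch expects matched (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("kabsch needs at least 3 point pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def rmsd(a, b):
    """Root-mean-square deviation between matched coordinate sets (Å)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
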