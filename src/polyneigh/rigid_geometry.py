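"""Rigid-body frame transforms for subtomogram particle orientations.

Orientations follow the intrinsic ZYZ Euler convention used by the common
subtomogram-alignment packages: the matrix ``M(rot, tilt, psi) =
Rz(psi) @ Ry(tilt) @ Rz(rot)`` maps vectors from the tomogram frame into the
particle reference frame.  For a membrane-bound ribosome the particle frame
has the membrane in the xy plane, with z along the outward membrane normal.

Angles are in degrees throughout.  Elementary rotations are active,
counterclockwise positive when viewed from the positive end of the axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "euler_to_rotation",
    "rotation_to_euler",
    "canonicalize_euler",
    "to_particle_frame",
]

_ORTHO_TOL = 1e-10


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_rotation(euler) -> np.ndarray:
    """Rotation operator mapping tomogram-frame vectors into the particle frame.

    Parameters
    ----------
    euler : sequence of 3 floats
        ``(rot, tilt, psi)`` in degrees.

    Returns
    -------
    ndarray, shape (3, 3)
        Proper orthonormal matrix ``Rz(psi) @ Ry(tilt) @ Rz(rot)``.
    """
    rot, tilt, psi = (float(a) for a in euler)
    if not all(np.isfinite(a) for a in (rot, tilt, psi)):
        raise ValueError(f"non-finite Euler angles: {(rot, tilt, psi)}")
    return _rot_z(psi) @ _rot_y(tilt) @ _rot_z(rot)


def euler_to_rotation_batch(eulers: np.ndarray) -> np.ndarray:
    """Vectorized :func:`euler_to_rotation` for an (N, 3) array of angles."""
    eulers = np.asarray(eulers, dtype=float)
    if not np.all(np.isfinite(eulers)):
        raise ValueError("non-finite Euler angles in batch")
    rot, tilt, psi = (np.radians(eulers[:, i]) for i in range(3))
    cr, sr = np.cos(rot), np.sin(rot)
    ct, st = np.cos(tilt), np.sin(tilt)
    cp, sp = np.cos(psi), np.sin(psi)
    m = np.empty((len(eulers), 3, 3))
    m[:, 0, 0] = cp * ct * cr - sp * sr
    m[:, 0, 1] = -cp * ct * sr - sp * cr
    m[:, 0, 2] = cp * st
    m[:, 1, 0] = sp * ct * cr + cp * sr
    m[:, 1, 1] = -sp * ct * sr + cp * cr
    m[:, 1, 2] = sp * st
    m[:, 2, 0] = -st * cr
    m[:, 2, 1] = st * sr
    m[:, 2, 2] = ct
    return m


def rotation_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """Invert :func:`euler_to_rotation`, returning canonical ``(rot, tilt, psi)``.

    Gimbal-locked matrices (tilt 0 or 180 deg) return psi = 0 with the full
    in-plane angle folded into rot.
    """
    m = np.asarray(matrix, dtype=float)
    validate_rotation(m)
    ct = np.clip(m[2, 2], -1.0, 1.0)
    tilt = np.degrees(np.arccos(ct))
    if min(abs(ct - 1.0), abs(ct + 1.0)) < 1e-12:
        # gimbal lock: only psi+rot (tilt 0) or rot-psi (tilt 180) is defined
        psi = 0.0
        if ct > 0:  # M = Rz(psi + rot)
            rot = np.degrees(np.arctan2(m[1, 0], m[0, 0]))
        else:  # M = Ry(180) @ Rz(rot - psi)
            rot = np.degrees(np.arctan2(m[1, 0], -m[0, 0]))
    else:
        psi = np.degrees(np.arctan2(m[1, 2], m[0, 2]))
        rot = np.degrees(np.arctan2(m[2, 1], -m[2, 0]))
    return canonicalize_euler((rot, tilt, psi))


def canonicalize_euler(euler) -> tuple[float, float, float]:
    """Canonicalize to rot, psi in [-180, 180) and tilt in [0, 180].

    A negative tilt is folded back using the ZYZ identity
    ``Ry(-t) = Rz(180) Ry(t) Rz(-180)``.
    """
    rot, tilt, psi = (float(a) for a in euler)
    if not all(np.isfinite(a) for a in (rot, tilt, psi)):
        raise ValueError(f"non-finite Euler angles: {(rot, tilt, psi)}")
    tilt = _wrap_half_open(tilt)
    if tilt < 0.0:
        tilt = -tilt
        rot -= 180.0
        psi += 180.0
    return _wrap_half_open(rot), tilt, _wrap_half_open(psi)


def _wrap_half_open(deg: float) -> float:
    """Wrap an angle to [-180, 180)."""
    return (deg + 180.0) % 360.0 - 180.0


def validate_rotation(matrix: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    """Raise if ``matrix`` is not a proper rotation (orthonormal, det +1)."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {m.shape}")
    if not np.allclose(m.T @ m, np.eye(3), atol=max(tol, 1e-9)):
        raise ValueError("matrix is not orthonormal")
    if abs(np.linalg.det(m) - 1.0) > max(tol, 1e-9):
        raise ValueError("matrix determinant is not +1 (improper rotation)")


def to_particle_frame(focal_position, focal_euler, other_position) -> np.ndarray:
    """Express ``other_position`` in the focal particle's reference frame.

    Returns ``M(focal_euler) @ (other_position - focal_position)`` -- the
    inter-particle vector rotated with the inverse of the focal particle's
    orientation, so that for a membrane-bound ribosome the xy plane of the
    result corresponds to the ER membrane.
    """
    focal_position = np.asarray(focal_position, dtype=float)
    other_position = np.asarray(other_position, dtype=float)
    return euler_to_rotation(focal_euler) @ (other_position - focal_position)
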