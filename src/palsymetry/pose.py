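"""Weak-perspective (scaled orthographic) camera model and pose estimation.

A 3D point ``X`` maps to the image as ``u = f * P R X + t`` where ``f`` is the
scale in pixels per model unit, ``R = Rz(roll) Ry(yaw) Rx(pitch)`` a proper
rotation, ``P = [[1,0,0],[0,1,0]]`` the orthographic projection and ``t`` a 2D
image-plane translation.  Only the image-plane component of a 3D translation
is observable under orthographic projection, so the pose stores the 2D
translation directly.

Image coordinates follow the landmark-file convention: origin top-left,
u right, v down, units pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "Pose",
    "PoseEstimate",
    "rotation_from_euler",
    "euler_from_rotation",
    "project",
    "estimate_pose",
]

#: Orthographic projection onto the image plane (drops depth).
P_ORTHO = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])

_GIMBAL_EPS = 1e-9


@dataclass(frozen=True)
class Pose:
    """Scale, Euler angles (radians) and image-plane translation (pixels)."""

    scale: float
    pitch: float = 0.0
    yaw: float = 0.0
    roll: float = 0.0
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64).reshape(2)
        )
        for name in ("scale", "pitch", "yaw", "roll"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"pose {name} must be finite")
        if not np.all(np.isfinite(self.translation)):
            raise ValueError("pose translation must be finite")
        if self.scale <= 0:
            raise ValueError(f"pose scale must be positive, got {self.scale}")

    def rotation(self) -> np.ndarray:
        return rotation_from_euler(self.pitch, self.yaw, self.roll)


class PoseEstimate(NamedTuple):
    pose: Pose
    residual: float  # root-mean-square reprojection error, pixels


def rotation_from_euler(pitch: float, yaw: float, roll: float) -> np.ndarray:
    """Proper rotation ``R = Rz(roll) @ Ry(yaw) @ Rx(pitch)`` (radians)."""
    for name, val in (("pitch", pitch), ("yaw", yaw), ("roll", roll)):
        if not math.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val}")
    ca, sa = math.cos(pitch), math.sin(pitch)
    cb, sb = math.cos(yaw), math.sin(yaw)
    cg, sg = math.cos(roll), math.sin(roll)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz @ ry @ rx


def euler_from_rotation(rot: np.ndarray) -> tuple[float, float, float]:
    """Recover ``(pitch, yaw, roll)`` from ``Rz(roll) Ry(yaw) Rx(pitch)``.

    At gimbal lock (``|cos(yaw)| < 1e-9``) the split between pitch and roll is
    unobservable; the branch is resolved deterministically by setting roll = 0.
    """
    rot = np.asarray(rot, dtype=np.float64)
    cy = math.hypot(rot[2, 1], rot[2, 2])  # |cos(yaw)|
    yaw = math.atan2(-rot[2, 0], cy)
    if cy < _GIMBAL_EPS:
        roll = 0.0
        pitch = math.atan2(-rot[1, 2], rot[1, 1])
    else:
        pitch = math.atan2(rot[2, 1], rot[2, 2])
        roll = math.atan2(rot[1, 0], rot[0, 0])
    return pitch, yaw, roll


def _as_points3d(points3d: np.ndarray) -> np.ndarray:
    pts = np.asarray(points3d, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] != 3:
        raise ValueError(f"points3d must have shape (3, n), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points3d contains non-finite coordinates")
    return pts


def project(points3d: np.ndarray, pose: Pose) -> np.ndarray:
    """Project ``(3, n)`` model points to ``(n, 2)`` pixel coordinates."""
    pts = _as_points3d(points3d)
    uv = pose.scale * (P_ORTHO @ pose.rotation() @ pts)
    return (uv + pose.translation[:, None]).T


def estimate_pose(points3d: np.ndarray, points2d: np.ndarray) -> PoseEstimate:
    """Closed-form scaled-orthographic pose from 2D-3D correspondences.

    Procedure: align centroids, solve the unconstrained 2x3 affine map by
    least squares, project it to the nearest matrix with orthonormal rows via
    SVD (completed to a proper rotation by the cross product, so the result
    can never be a reflection), then refit scale and translation in closed
    form.  Exact on noiseless weak-perspective observations.

    Requires at least 3 non-collinear 3D points; collinear or coincident
    configurations raise :class:`DegenerateGeometryError`.
    """
    pts3 = _as_points3d(points3d)
    obs = np.asarray(points2d, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[1] != 2:
        raise ValueError(f"points2d must have shape (n, 2), got {obs.shape}")
    if not np.all(np.isfinite(obs)):
        raise ValueError("points2d contains non-finite coordinates")
    n = pts3.shape[1]
    if obs.shape[0] != n:
        raise ValueError(f"{n} 3D points but {obs.shape[0]} observations")
    if n < 3:
        raise ValueError(f"need at least 3 correspondences, got {n}")

    u = obs.T  # (2, n)
    xc = pts3 - pts3.mean(axis=1, keepdims=True)
    uc = u - u.mean(axis=1, keepdims=True)

    sv = np.linalg.svd(xc, compute_uv=False)
    if sv[1] <= 1e-10 * max(sv[0], 1.0):
        raise DegenerateGeometryError(
            "3D points are collinear or coincident; pose is unconstrained"
        )

    # Unconstrained affine map (lstsq tolerates coplanar rank-2 clouds).
    affine, *_ = np.linalg.lstsq(xc.T, uc.T, rcond=None)
    affine = affine.T  # (2, 3)

    uu, sing, vt = np.linalg.svd(affine, full_matrices=False)
    if sing[0] <= 0:
        raise DegenerateGeometryError("observations have no image-plane spread")
    r2 = uu @ vt  # orthonormal rows
    r3 = np.cross(r2[0], r2[1])
    rot = np.vstack([r2, r3])  # det = +1 by construction

    mapped = r2 @ xc
    denom = float(np.sum(mapped * mapped))
    if denom <= 0:
        raise DegenerateGeometryError("rotated 3D points collapse on the image plane")
    scale = float(np.sum(uc * mapped)) / denom
    if scale <= 0:
        raise DegenerateGeometryError(
            "negative or zero scale; observations are inconsistent with a "
            "scaled-orthographic camera"
        )
    translation = u.mean(axis=1) - scale * (r2 @ pts3.mean(axis=1))
    pitch, yaw, roll = euler_from_rotation(rot)
    pose = Pose(scale=scale, pitch=pitch, yaw=yaw, roll=roll, translation=translation)
    reproj = project(pts3, pose)
    residual = float(np.sqrt(np.mean(np.sum((reproj - obs) ** 2, axis=1))))
    return PoseEstimate(pose=pose, residual=residual)
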