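"""Rigid-body mathematics and geometric primitive fitting.

This module provides the low-level machinery shared by the whole toolkit:

* Cardan z-x-y angle conventions used to report joint rotations
  (flexion/extension, adduction/abduction, internal/external rotation);
* :class:`RigidTransform`, the pose of a segment anatomical frame in the
  laboratory frame;
* weighted point-set registration (Procrustes/Kabsch with a reflection
  guard), the work-horse of single-body optimization;
* orthogonal-distance fits of sphere, cylinder and plane primitives used
  to locate reference joint centres on bone-surface point clouds.

Units are millimetres for lengths and degrees for angles throughout.

The Cardan convention is *intrinsic* (body-fixed) z-x-y applied to the
relative rotation ``R_parent.T @ R_child``: the first rotation (about z,
the laterally directed axis) is flexion/extension, the second (about the
once-rotated x) is adduction/abduction, the third (about the twice-rotated
y) is internal/external rotation.  Composition order is therefore
``Rz(alpha) @ Rx(beta) @ Ry(gamma)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    ConvergenceError,
    DegenerateGeometryError,
    GimbalLockError,
    InvalidArgumentError,
    UnderdeterminedError,
)

__all__ = [
    "RigidTransform",
    "SphereFitResult",
    "CylinderFitResult",
    "PlaneFitResult",
    "cardan_zxy_to_rotation",
    "rotation_to_cardan_zxy",
    "weighted_rigid_fit",
    "fit_sphere",
    "fit_cylinder",
    "fit_plane",
]

# Iterative geometric fits stop on a 1e-10 relative cost change, capped at
# 200 iterations; these are deliberately tight because downstream joint
# centres are compared at sub-millimetre tolerances.
_FTOL = 1e-10
_XTOL = 1e-12
_MAX_ITER = 200

_GIMBAL_TOL = 1e-8
_ROTATION_ATOL = 1e-7


def _as_points(points, min_points: int, name: str = "points") -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidArgumentError(f"{name} must have shape (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidArgumentError(f"{name} contain non-finite coordinates")
    if pts.shape[0] < min_points:
        raise UnderdeterminedError(
            f"{name}: need at least {min_points} points, got {pts.shape[0]}"
        )
    return pts


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidArgumentError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=_ROTATION_ATOL):
        raise InvalidArgumentError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise InvalidArgumentError("matrix is a reflection (det < 0), not a rotation")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation then translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise InvalidArgumentError("translation has non-finite components")
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InvalidArgumentError(f"homogeneous matrix must be 4x4, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3])

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        """Transform one point (3,) or a stack (n, 3)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply *other* first, then *self*."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


def cardan_zxy_to_rotation(angles_deg) -> np.ndarray:
    """Compose a rotation from intrinsic z-x-y Cardan angles.

    Parameters
    ----------
    angles_deg : array-like of 3 floats
        ``(flexion_extension, adduction_abduction, internal_external)`` in
        degrees: rotations about z, then the rotated x, then the twice
        rotated y.

    Returns
    -------
    (3, 3) proper rotation matrix ``Rz(a) @ Rx(b) @ Ry(g)``.
    """
    a = np.asarray(angles_deg, dtype=float).reshape(3)
    if not np.all(np.isfinite(a)):
        raise InvalidArgumentError("Cardan angles must be finite")
    ca, cb, cg = np.cos(np.radians(a))
    sa, sb, sg = np.sin(np.radians(a))
    return np.array(
        [
            [ca * cg - sa * sb * sg, -sa * cb, ca * sg + sa * sb * cg],
            [sa * cg + ca * sb * sg, ca * cb, sa * sg - ca * sb * cg],
            [-cb * sg, sb, cb * cg],
        ]
    )


def rotation_to_cardan_zxy(R) -> np.ndarray:
    """Decompose a rotation into intrinsic z-x-y Cardan angles (degrees).

    The middle angle (adduction/abduction) is returned in [-90, 90] deg.
    Raises :class:`GimbalLockError` when |sin(beta)| is within 1e-8 of 1,
    where the decomposition is not unique; normal gait stays far from this.
    """
    R = _check_rotation(R)
    sb = R[2, 1]
    if abs(sb) >= 1.0 - _GIMBAL_TOL:
        raise GimbalLockError(
            "adduction/abduction at +/-90 deg: z-x-y Cardan angles undefined"
        )
    beta = np.arcsin(sb)
    alpha = np.arctan2(-R[0, 1], R[1, 1])
    gamma = np.arctan2(-R[2, 0], R[2, 2])
    return np.degrees(np.array([alpha, beta, gamma]))


def weighted_rigid_fit(template, observed, weights=None) -> RigidTransform:
    """Closed-form weighted Procrustes registration.

    Finds the rigid motion ``(R, t)`` globally minimizing
    ``sum_i w_i * ||R @ p_i + t - q_i||^2`` over corresponding points
    ``p_i`` (template) and ``q_i`` (observed), via the weighted Kabsch
    SVD solution with a reflection guard (the sign of the smallest singular
    direction is flipped when the candidate solution is a reflection).

    Markers with zero weight are excluded exactly; at least three
    non-collinear positively weighted points are required.
    """
    p = _as_points(template, 1, "template")
    q = _as_points(observed, 1, "observed")
    if p.shape != q.shape:
        raise InvalidArgumentError("template and observed must have equal shapes")
    n = p.shape[0]
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float).reshape(n)
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise InvalidArgumentError("weights must be finite and non-negative")
    effective = w > 0
    if np.count_nonzero(effective) < 3:
        raise UnderdeterminedError("rigid fit needs >= 3 points with positive weight")
    p, q, w = p[effective], q[effective], w[effective]

    wsum = w.sum()
    p_bar = (w[:, None] * p).sum(axis=0) / wsum
    q_bar = (w[:, None] * q).sum(axis=0) / wsum
    pc = p - p_bar
    qc = q - q_bar
    # collinearity of the effective template points makes the rotation
    # about the line unobservable
    if np.linalg.matrix_rank(np.sqrt(w)[:, None] * pc, tol=1e-9 * max(1.0, np.abs(pc).max())) < 2:
        raise DegenerateGeometryError("effective points are collinear")

    H = (w[:, None] * pc).T @ qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = q_bar - R @ p_bar
    return RigidTransform(R, t)


@dataclass(frozen=True)
class SphereFitResult:
    centre: np.ndarray
    radius: float
    rms_residual: float


@dataclass(frozen=True)
class CylinderFitResult:
    axis_point: np.ndarray  # point on the axis at the middle of the data extent
    axis_direction: np.ndarray  # unit vector
    radius: float
    axis_extent: tuple  # (smin, smax) projections relative to axis_point, mm
    rms_residual: float
    iterations: int = field(default=0, compare=False)


@dataclass(frozen=True)
class PlaneFitResult:
    point: np.ndarray
    normal: np.ndarray
    rms_residual: float


def _algebraic_sphere(points: np.ndarray):
    # ||p||^2 = 2 c.p + (r^2 - ||c||^2): linear in (c, k)
    A = np.hstack([2.0 * points, np.ones((points.shape[0], 1))])
    b = (points**2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError("points are coplanar: sphere fit is degenerate")
    c = sol[:3]
    r2 = sol[3] + c @ c
    if r2 <= 0:
        raise DegenerateGeometryError("algebraic sphere fit gave non-positive radius")
    return c, np.sqrt(r2)


def fit_sphere(points) -> SphereFitResult:
    """Orthogonal-distance sphere fit, minimizing ``sum (||p_i - c|| - r)^2``.

    An algebraic (linear least squares) fit provides the initial guess for
    the geometric refinement.  Requires >= 4 non-coplanar points.
    """
    pts = _as_points(points, 4)
    c0, r0 = _algebraic_sphere(pts)

    def resid(x):
        return np.linalg.norm(pts - x[:3], axis=1) - x[3]

    sol = least_squares(
        resid, np.append(c0, r0), ftol=_FTOL, xtol=_XTOL, max_nfev=_MAX_ITER * 5
    )
    r = sol.x[3]
    if r <= 0:
        raise DegenerateGeometryError("sphere fit collapsed to non-positive radius")
    res = resid(sol.x)
    return SphereFitResult(sol.x[:3], float(r), float(np.sqrt(np.mean(res**2))))


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    st, ct = np.sin(theta), np.cos(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), ct])


def fit_cylinder(points, init_axis) -> CylinderFitResult:
    """Orthogonal-distance cylinder fit, minimizing ``sum (d_i - r)^2`` where
    ``d_i`` is point-to-axis distance.

    The axis direction is parameterized by spherical angles seeded from
    ``init_axis``; the axis point is constrained to the plane through the
    data centroid perpendicular to the axis, removing the along-axis
    indeterminacy.  The returned ``axis_point`` sits at the midpoint of the
    projected extent of the input points — the "centroid" of the fitted
    primitive in the sense used for the stifle joint centre.
    """
    pts = _as_points(points, 6)
    a0 = np.asarray(init_axis, dtype=float).reshape(3)
    n0 = np.linalg.norm(a0)
    if n0 == 0 or not np.all(np.isfinite(a0)):
        raise InvalidArgumentError("init_axis must be a non-zero finite vector")
    a0 = a0 / n0

    centroid = pts.mean(axis=0)
    centred = pts - centroid
    svals = np.linalg.svd(centred, compute_uv=False)
    scale = max(np.abs(centred).max(), 1.0)
    if svals[1] < 1e-9 * scale:
        raise DegenerateGeometryError("points lie on a single line: cylinder degenerate")

    theta0 = float(np.arccos(np.clip(a0[2], -1, 1)))
    phi0 = float(np.arctan2(a0[1], a0[0]))

    def unpack(x):
        d = _axis_from_angles(x[0], x[1])
        # orthonormal basis of the plane perpendicular to d
        ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(d, ref)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        c = centroid + x[2] * u + x[3] * v
        return c, d, x[4]

    def resid(x):
        c, d, r = unpack(x)
        rel = pts - c
        dist = np.linalg.norm(rel - np.outer(rel @ d, d), axis=1)
        return dist - r

    rel0 = centred - np.outer(centred @ a0, a0)
    r0 = float(np.mean(np.linalg.norm(rel0, axis=1)))
    x0 = np.array([theta0, phi0, 0.0, 0.0, r0])
    sol = least_squares(resid, x0, ftol=_FTOL, xtol=_XTOL, max_nfev=_MAX_ITER * 10)
    if not sol.success:
        raise ConvergenceError(
            f"cylinder fit did not converge: {sol.message}", iterations=sol.nfev
        )
    c, d, r = unpack(sol.x)
    if r <= 0:
        raise DegenerateGeometryError("cylinder fit collapsed to non-positive radius")
    s = (pts - c) @ d
    smid = 0.5 * (s.min() + s.max())
    axis_point = c + smid * d
    res = resid(sol.x)
    return CylinderFitResult(
        axis_point=axis_point,
        axis_direction=d,
        radius=float(r),
        axis_extent=(float(s.min() - smid), float(s.max() - smid)),
        rms_residual=float(np.sqrt(np.mean(res**2))),
        iterations=int(sol.nfev),
    )


def fit_plane(points) -> PlaneFitResult:
    """Total-least-squares plane: the normal is the smallest principal
    direction of the centred covariance; the fit point is the centroid."""
    pts = _as_points(points, 3)
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    _, svals, Vt = np.linalg.svd(centred, full_matrices=False)
    scale = max(np.abs(centred).max(), 1.0)
    if svals[1] < 1e-9 * scale:
        raise DegenerateGeometryError("points are collinear: plane undefined")
    normal = Vt[2]
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFitResult(point=centroid, normal=normal, rms_residual=rms)
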