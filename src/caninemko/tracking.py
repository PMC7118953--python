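"""Segment pose estimation from skin-marker trajectories.

Two estimators are provided, both presented as model objects whose
``fit()`` returns a :class:`TrackingResult`:

* :class:`SingleBodyOptimizer` (SO) — each segment is registered to its
  marker template independently per frame by weighted Procrustes,
  minimizing the deformation of the measured marker array from its
  calibration shape.  No joint constraint links the segments, so rigid
  components of soft tissue artefact pass straight into the poses.

* :class:`MultibodyOptimizer` (MKO) — the whole pelvis–femur–tibia chain
  is fitted at once in minimal coordinates: 6 degrees of freedom pose the
  pelvis, 3 rotate the femur about the hip joint centre and 3 rotate the
  tibia about the stifle joint centre.  Ball-and-socket constraints are
  therefore satisfied exactly by construction.  The weighted marker
  residual is minimized per frame with Levenberg–Marquardt, warm-started
  from the previous frame (the first frame starts from the SO solution
  projected onto the joint-centre chain).

Rotational degrees of freedom are Cardan z-x-y triplets in degrees;
translations are millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .bodymodel import MultibodyModel, SEGMENTS
from .errors import InvalidArgumentError
from .geometry import (
    RigidTransform,
    cardan_zxy_to_rotation,
    rotation_to_cardan_zxy,
    weighted_rigid_fit,
)

__all__ = [
    "MarkerTrajectorySet",
    "TrackingResult",
    "SingleBodyOptimizer",
    "MultibodyOptimizer",
    "so_track",
    "mko_track",
    "mko_solve_frame",
    "forward_kinematics",
    "dof_from_poses",
    "local_marker_displacement",
    "weights_from_displacement",
]

_GIMBAL_WARN_DEG = 80.0


@dataclass
class MarkerTrajectorySet:
    """Time-indexed named marker positions with per-frame visibility.

    Attributes
    ----------
    rate : float
        Sampling rate, Hz.
    markers : tuple of str
        Marker names, fixing the column order of ``positions``.
    positions : (n_frames, n_markers, 3) float array, mm
        Laboratory-frame coordinates; values at invisible samples are
        ignored (and may be NaN).
    visible : (n_frames, n_markers) bool array
    """

    rate: float
    markers: tuple
    positions: np.ndarray
    visible: np.ndarray

    def __post_init__(self):
        self.markers = tuple(self.markers)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise InvalidArgumentError(
                f"positions must be (n_frames, n_markers, 3), got {self.positions.shape}"
            )
        if self.positions.shape[1] != len(self.markers):
            raise InvalidArgumentError("positions width does not match marker count")
        if self.visible is None:
            self.visible = np.all(np.isfinite(self.positions), axis=2)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.visible.shape != self.positions.shape[:2]:
            raise InvalidArgumentError("visible mask shape mismatch")
        if self.rate <= 0:
            raise InvalidArgumentError("sampling rate must be positive")
        vis_vals = self.positions[self.visible]
        if vis_vals.size and not np.all(np.isfinite(vis_vals)):
            raise InvalidArgumentError("a visible marker sample is non-finite")

    @classmethod
    def from_dict(cls, rate: float, frames: list) -> "MarkerTrajectorySet":
        """Build from a list of per-frame ``{marker: (x, y, z)}`` dicts."""
        names = sorted({m for f in frames for m in f})
        pos = np.full((len(frames), len(names), 3), np.nan)
        vis = np.zeros((len(frames), len(names)), dtype=bool)
        for k, f in enumerate(frames):
            for j, name in enumerate(names):
                if name in f and f[name] is not None:
                    pos[k, j] = f[name]
                    vis[k, j] = True
        return cls(rate=rate, markers=tuple(names), positions=pos, visible=vis)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def index(self, marker: str) -> int:
        try:
            return self.markers.index(marker)
        except ValueError:
            raise KeyError(f"marker '{marker}' not in trajectory set") from None

    def trajectory(self, marker: str) -> np.ndarray:
        """(n_frames, 3) positions of one marker (NaN where invisible)."""
        j = self.index(marker)
        out = self.positions[:, j].copy()
        out[~self.visible[:, j]] = np.nan
        return out

    def slice(self, start: int, stop: int) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            rate=self.rate,
            markers=self.markers,
            positions=self.positions[start:stop],
            visible=self.visible[start:stop],
        )


@dataclass
class TrackingResult:
    """Per-frame segment poses with fit diagnostics.

    ``rotations[seg]`` is (n_frames, 3, 3), ``translations[seg]`` is
    (n_frames, 3); invalid frames hold NaN and are flagged in
    ``frame_valid``.  For the multibody estimator ``dof`` holds the
    12-vector of generalized coordinates per frame.
    """

    method: str
    rate: float
    rotations: dict
    translations: dict
    residual_rms: np.ndarray  # weighted RMS marker residual per frame, mm
    frame_valid: np.ndarray
    converged: np.ndarray
    iterations: np.ndarray
    model: MultibodyModel = field(repr=False, default=None)
    dof: np.ndarray | None = field(repr=False, default=None)
    segment_valid: dict = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return self.residual_rms.shape[0]

    def pose(self, frame: int, segment: str) -> RigidTransform:
        return RigidTransform(
            self.rotations[segment][frame], self.translations[segment][frame]
        )

    def joint_centre_gap(self) -> np.ndarray:
        """(n_frames, 2) lab-frame distances between the two expressions of
        the hip and stifle centres.  Zero (to rounding) under MKO; free to
        grow under SO, where it measures the artefact the constraint would
        have absorbed."""
        c = self.model.centres
        gaps = np.full((self.n_frames, 2), np.nan)
        ok = self.frame_valid
        for k in np.nonzero(ok)[0]:
            p = self.pose(k, "pelvis")
            f = self.pose(k, "femur")
            t = self.pose(k, "tibia")
            gaps[k, 0] = np.linalg.norm(p.apply(c.hjc_in_pelvis) - f.apply(c.hjc_in_femur))
            gaps[k, 1] = np.linalg.norm(f.apply(c.sjc_in_femur) - t.apply(c.sjc_in_tibia))
        return gaps

    def summary(self) -> str:
        ok = self.frame_valid
        lines = [
            f"{'Multibody' if self.method == 'mko' else 'Single-body'} tracking result",
            "=" * 46,
            f"frames:            {self.n_frames} ({int(ok.sum())} valid)",
            f"sampling rate:     {self.rate:g} Hz",
            f"converged frames:  {int(self.converged[ok].sum())}/{int(ok.sum())}",
            f"marker residual:   {np.nanmean(self.residual_rms[ok]):.3f} mm RMS (mean over frames)",
        ]
        if ok.any():
            gaps = self.joint_centre_gap()
            lines.append(
                f"hip/stifle centre gap: {np.nanmax(gaps[:, 0]):.2e} / "
                f"{np.nanmax(gaps[:, 1]):.2e} mm (max)"
            )
        if self.method == "mko":
            lines.append(f"mean LM iterations: {np.mean(self.iterations[ok]):.1f}")
        return "\n".join(lines)


def _resolve_weights(model: MultibodyModel, weights: dict | None) -> dict:
    w = dict(model.weights)
    if weights is not None:
        w.update({k: float(v) for k, v in weights.items()})
    for seg in SEGMENTS:
        if not any(w.get(n, 0.0) > 0 for n in model.dynamic_markers[seg]):
            raise InvalidArgumentError(f"segment '{seg}' has no positively weighted marker")
    return w


class _SegmentView:
    """Cached per-segment indexing of trajectories against the model."""

    def __init__(self, traj: MarkerTrajectorySet, model: MultibodyModel, weights: dict):
        self.segments = {}
        for seg in SEGMENTS:
            names, template = model.dynamic_template(seg)
            present = [i for i, n in enumerate(names) if n in traj.markers]
            names = [names[i] for i in present]
            self.segments[seg] = {
                "names": names,
                "template": template[present],
                "cols": np.array([traj.index(n) for n in names], dtype=int),
                "weights": np.array([weights[n] for n in names]),
            }
        self.traj = traj


class SingleBodyOptimizer:
    """Per-segment rigid registration of marker templates (SO).

    Parameters
    ----------
    trajectories : MarkerTrajectorySet
    model : MultibodyModel
    weights : dict, optional
        Per-marker weights overriding the model's defaults.
    """

    def __init__(self, trajectories, model, weights=None):
        self.trajectories = trajectories
        self.model = model
        self.weights = _resolve_weights(model, weights)
        self._view = _SegmentView(trajectories, model, self.weights)

    def fit(self) -> TrackingResult:
        traj = self.trajectories
        n = traj.n_frames
        rotations = {s: np.full((n, 3, 3), np.nan) for s in SEGMENTS}
        translations = {s: np.full((n, 3), np.nan) for s in SEGMENTS}
        seg_valid = {s: np.zeros(n, dtype=bool) for s in SEGMENTS}
        rms = np.full(n, np.nan)

        for k in range(n):
            sq_sum, w_cnt = 0.0, 0
            for seg in SEGMENTS:
                sv = self._view.segments[seg]
                vis = traj.visible[k, sv["cols"]]
                usable = vis & (sv["weights"] > 0)
                if np.count_nonzero(usable) < 3:
                    continue
                obs = traj.positions[k, sv["cols"][usable]]
                tmpl = sv["template"][usable]
                w = sv["weights"][usable]
                try:
                    tf = weighted_rigid_fit(tmpl, obs, w)
                except Exception:
                    continue
                rotations[seg][k] = tf.rotation
                translations[seg][k] = tf.translation
                seg_valid[seg][k] = True
                d = tf.apply(tmpl) - obs
                sq_sum += float((w * (d**2).sum(axis=1)).sum())
                w_cnt += float(w.sum())
            if w_cnt > 0:
                rms[k] = np.sqrt(sq_sum / w_cnt)

        frame_valid = np.logical_and.reduce([seg_valid[s] for s in SEGMENTS])
        return TrackingResult(
            method="so",
            rate=traj.rate,
            rotations=rotations,
            translations=translations,
            residual_rms=rms,
            frame_valid=frame_valid,
            converged=frame_valid.copy(),
            iterations=np.zeros(n, dtype=int),
            model=self.model,
            segment_valid=seg_valid,
        )


def forward_kinematics(q, centres):
    """Segment poses from the 12 generalized coordinates.

    ``q`` = (pelvis translation x3 mm, pelvis Cardan z-x-y x3 deg,
    femur Cardan triplet about the hip x3 deg, tibia Cardan triplet about
    the stifle x3 deg).  Returns ``{segment: (R, t)}`` in the lab frame.
    The hip and stifle spherical constraints hold by construction.
    """
    q = np.asarray(q, dtype=float).reshape(12)
    R_p = cardan_zxy_to_rotation(q[3:6])
    t_p = q[0:3]
    hjc_lab = R_p @ centres.hjc_in_pelvis + t_p
    R_f = R_p @ cardan_zxy_to_rotation(q[6:9])
    t_f = hjc_lab - R_f @ centres.hjc_in_femur
    sjc_lab = R_f @ centres.sjc_in_femur + t_f
    R_t = R_f @ cardan_zxy_to_rotation(q[9:12])
    t_t = sjc_lab - R_t @ centres.sjc_in_tibia
    return {"pelvis": (R_p, t_p), "femur": (R_f, t_f), "tibia": (R_t, t_t)}


def dof_from_poses(pelvis: RigidTransform, femur: RigidTransform, tibia: RigidTransform):
    """Project three independent segment poses onto the 12-coordinate chain
    (used to seed the multibody solve from a single-body solution).  The
    rotational coordinates are exact; translation mismatch at the joints is
    discarded."""
    q = np.empty(12)
    q[0:3] = pelvis.translation
    q[3:6] = rotation_to_cardan_zxy(pelvis.rotation)
    q[6:9] = rotation_to_cardan_zxy(pelvis.rotation.T @ femur.rotation)
    q[9:12] = rotation_to_cardan_zxy(femur.rotation.T @ tibia.rotation)
    return q


def _frame_residual_builder(view: _SegmentView, frame: int):
    """Residual closure for one frame; rows for invisible or zero-weight
    markers are dropped."""
    traj = view.traj
    parts = []
    for seg in SEGMENTS:
        sv = view.segments[seg]
        usable = traj.visible[frame, sv["cols"]] & (sv["weights"] > 0)
        parts.append(
            (
                seg,
                sv["template"][usable],
                traj.positions[frame, sv["cols"][usable]],
                np.sqrt(sv["weights"][usable])[:, None],
                float(sv["weights"][usable].sum()),
            )
        )
    n_rows = sum(p[1].shape[0] for p in parts)
    w_total = sum(p[4] for p in parts)

    def residual(q, centres):
        poses = forward_kinematics(q, centres)
        out = []
        for seg, tmpl, obs, sqw, _ in parts:
            if tmpl.shape[0] == 0:
                continue
            R, t = poses[seg]
            out.append((sqw * (tmpl @ R.T + t - obs)).ravel())
        return np.concatenate(out) if out else np.zeros(0)

    return residual, n_rows, w_total, parts


def mko_solve_frame(
    trajectories: MarkerTrajectorySet,
    frame: int,
    model: MultibodyModel,
    init,
    weights: dict | None = None,
    max_iter: int = 200,
):
    """Levenberg–Marquardt solve of the 12-coordinate chain for one frame.

    Returns ``(q, residual_rms_mm, n_evals, converged)``.  Convergence is a
    relative cost change below 1e-10 or a small gradient; the iteration cap
    flags (never silently returns) a non-converged frame.
    """
    w = _resolve_weights(model, weights)
    view = _SegmentView(trajectories, model, w)
    residual, n_rows, w_total, _ = _frame_residual_builder(view, frame)
    if n_rows < 6:
        raise InvalidArgumentError(
            f"frame {frame}: only {n_rows} usable markers; at least 6 are required"
        )
    q0 = np.asarray(init, dtype=float).reshape(12)
    if not np.all(np.isfinite(q0)):
        raise InvalidArgumentError("initial DOF vector must be finite")
    centres = model.centres
    sol = least_squares(
        residual,
        q0,
        args=(centres,),
        method="lm",
        diff_step=1e-6,
        ftol=1e-10,
        xtol=1e-12,
        gtol=1e-8,
        max_nfev=max_iter * 13,
    )
    r = sol.fun
    rms = float(np.sqrt((r @ r) / w_total))
    converged = bool(sol.status > 0)
    if np.any(np.abs(sol.x[[4, 7, 10]]) > _GIMBAL_WARN_DEG):
        warnings.warn(
            f"frame {frame}: adduction/abduction beyond {_GIMBAL_WARN_DEG} deg, "
            "approaching the z-x-y gimbal singularity"
        )
    return sol.x, rms, int(sol.nfev), converged


class MultibodyOptimizer:
    """Global 12-DOF fit of the jointed chain to measured markers (MKO).

    Parameters
    ----------
    trajectories : MarkerTrajectorySet
    model : MultibodyModel
    weights : dict, optional
        Per-marker weights overriding the model's (e.g. the reciprocal of
        local marker displacement).
    """

    def __init__(self, trajectories, model, weights=None):
        self.trajectories = trajectories
        self.model = model
        self.weights = _resolve_weights(model, weights)
        self._view = _SegmentView(trajectories, model, self.weights)

    def _initial_dof(self, so_result: TrackingResult) -> np.ndarray:
        k0 = int(np.nonzero(so_result.frame_valid)[0][0]) if so_result.frame_valid.any() else None
        if k0 is None:
            raise InvalidArgumentError(
                "no frame has three visible markers on every segment; "
                "cannot initialize the multibody solve"
            )
        return k0, dof_from_poses(
            so_result.pose(k0, "pelvis"),
            so_result.pose(k0, "femur"),
            so_result.pose(k0, "tibia"),
        )

    def fit(self, so_result: TrackingResult | None = None) -> TrackingResult:
        traj = self.trajectories
        n = traj.n_frames
        if so_result is None:
            so_result = SingleBodyOptimizer(traj, self.model, self.weights).fit()
        _, q_prev = self._initial_dof(so_result)

        rotations = {s: np.full((n, 3, 3), np.nan) for s in SEGMENTS}
        translations = {s: np.full((n, 3), np.nan) for s in SEGMENTS}
        rms = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        converged = np.zeros(n, dtype=bool)
        iters = np.zeros(n, dtype=int)
        dof = np.full((n, 12), np.nan)

        for k in range(n):
            try:
                q, r, nev, conv = mko_solve_frame(
                    traj, k, self.model, q_prev, self.weights
                )
            except InvalidArgumentError:
                continue
            dof[k] = q
            rms[k] = r
            iters[k] = nev
            converged[k] = conv
            valid[k] = True
            poses = forward_kinematics(q, self.model.centres)
            for seg in SEGMENTS:
                rotations[seg][k], translations[seg][k] = poses[seg]
            q_prev = q

        return TrackingResult(
            method="mko",
            rate=traj.rate,
            rotations=rotations,
            translations=translations,
            residual_rms=rms,
            frame_valid=valid,
            converged=converged,
            iterations=iters,
            model=self.model,
            dof=dof,
        )


def so_track(trajectories, model, weights=None) -> TrackingResult:
    """Single-body (unconstrained, per-segment) tracking of a whole trial."""
    return SingleBodyOptimizer(trajectories, model, weights).fit()


def mko_track(trajectories, model, weights=None) -> TrackingResult:
    """Multibody (joint-constrained) tracking of a whole trial."""
    return MultibodyOptimizer(trajectories, model, weights).fit()


def local_marker_displacement(
    trajectories: MarkerTrajectorySet,
    so_result: TrackingResult,
    model: MultibodyModel,
) -> dict:
    """Average displacement of each marker about its mean position in the
    (single-body-estimated) segment frame, mm.

    This is the observable surrogate for soft tissue artefact magnitude:
    each measured marker position is expressed in its segment's
    SO-determined frame per frame, and the displacement is the mean
    distance from the temporal mean of those local positions.  A rigid
    whole-cluster artefact moves the estimated frame along with the
    markers and is invisible to this metric, which therefore
    underestimates the full artefact.
    """
    out = {}
    for seg in SEGMENTS:
        names, _ = model.dynamic_template(seg)
        valid = so_result.segment_valid[seg] if so_result.segment_valid is not None else so_result.frame_valid
        R = so_result.rotations[seg]
        t = so_result.translations[seg]
        for name in names:
            if name not in trajectories.markers:
                continue
            j = trajectories.index(name)
            frames = np.nonzero(valid & trajectories.visible[:, j])[0]
            if frames.size == 0:
                warnings.warn(f"marker '{name}' never visible; excluded from displacement map")
                continue
            lab = trajectories.positions[frames, j]
            local = np.einsum("kij,kj->ki", R[frames].transpose(0, 2, 1), lab - t[frames])
            mean_local = local.mean(axis=0)
            out[name] = float(np.mean(np.linalg.norm(local - mean_local, axis=1)))
    return out


def weights_from_displacement(displacements: dict, floor: float = 0.5) -> dict:
    """Marker weights as the reciprocal of local marker displacement.

    ``w_i = 1 / max(d_i, floor)``, then normalized so the mean weight is 1
    (keeping weighted and unweighted costs on the same scale).  The floor
    (mm) prevents a near-rigid marker from dominating the cost.
    """
    if not displacements:
        raise InvalidArgumentError("displacement map is empty")
    if any(d < 0 or not np.isfinite(d) for d in displacements.values()):
        raise InvalidArgumentError("displacements must be finite and >= 0")
    raw = {k: 1.0 / max(d, floor) for k, d in displacements.items()}
    mean = sum(raw.values()) / len(raw)
    return {k: v / mean for k, v in raw.items()}
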