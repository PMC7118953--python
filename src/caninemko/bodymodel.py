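"""Subject-specific multibody model of the canine pelvic limb.

The model is built from a single standing calibration in which 15 named
skin markers are visible: 12 anatomical landmarks, two cranial-thigh
tracking markers and one dorsal foot marker used only for gait events.
From the calibration this module derives

* per-segment anatomical frames (AF) for pelvis, femur (thigh) and tibia
  (crus), with x cranial, y proximal and z lateral (right limb),
* time-invariant marker templates (local marker coordinates in each AF),
* hip and stifle joint centres — predicted from landmark regression or
  measured from bone-surface point clouds — expressed in both adjacent
  AFs so that spherical joint constraints can link the chain.

The medial epicondyle and medial malleolus are calibration-only markers:
they are removed for dynamic trials, leaving four tracking markers per
segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateGeometryError,
    InvalidArgumentError,
    MissingLandmarkError,
    ModelValidityError,
)
from .geometry import (
    CylinderFitResult,
    RigidTransform,
    SphereFitResult,
    fit_cylinder,
    fit_plane,
    fit_sphere,
)

SEGMENTS = ("pelvis", "femur", "tibia")

PELVIC_LANDMARKS = ("L_ILIAC_CREST", "R_ILIAC_CREST", "L_ISCHIAL_TUB", "R_ISCHIAL_TUB")

#: marker -> segment assignment used for templates and tracking
SEGMENT_MARKERS: dict[str, tuple[str, ...]] = {
    "pelvis": PELVIC_LANDMARKS,
    "femur": ("GT", "LAT_EPICONDYLE", "MED_EPICONDYLE", "THIGH_TRACK_1", "THIGH_TRACK_2"),
    "tibia": ("FIB_HEAD", "PROX_TIB_CREST", "DIST_TIB_CREST", "LAT_MALLEOLUS", "MED_MALLEOLUS"),
}

#: medial markers are placed for calibration only and removed before
#: dynamic acquisition
MEDIAL_MARKERS = ("MED_EPICONDYLE", "MED_MALLEOLUS")

#: the foot marker defines paw-contact timing; it belongs to no modelled segment
EVENT_MARKER = "FOOT"

CALIBRATION_LANDMARKS = tuple(
    name for seg in SEGMENTS for name in SEGMENT_MARKERS[seg]
)

_CONSISTENCY_TOL = 1e-9


def _get(landmarks: dict, name: str) -> np.ndarray:
    try:
        return np.asarray(landmarks[name], dtype=float).reshape(3)
    except KeyError:
        raise MissingLandmarkError(f"required landmark '{name}' is missing") from None


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise DegenerateGeometryError(f"{what}: defining points are coincident/collinear")
    return v / n


def _frame_from_axes(origin, y_hat, z_raw, what: str) -> RigidTransform:
    """Right-handed frame with exact y, z orthogonalized against y, x = y × z."""
    z_hat = _unit(z_raw - (z_raw @ y_hat) * y_hat, what)
    x_hat = np.cross(y_hat, z_hat)
    return RigidTransform(np.column_stack([x_hat, y_hat, z_hat]), origin)


def build_anatomical_frames(landmarks: dict) -> dict[str, RigidTransform]:
    """Construct the pelvis, femur and tibia anatomical frames (lab frame).

    Conventions (right pelvic limb): x cranial, y proximal, z lateral.

    * pelvis — origin at the midpoint of the iliac crests; x from the
      mid-ischial-tuberosity point toward the mid-iliac-crest point; z
      lateral, orthogonalized against the left-to-right iliac direction.
    * femur — origin at the midpoint of the epicondyles; y toward the
      greater trochanter; z lateral in the plane (origin, GT, lateral
      epicondyle).
    * tibia — origin at the midpoint of the malleoli; y toward the midpoint
      of the fibular head and proximal tibial crest; z lateral in the plane
      containing the lateral malleolus.
    """
    l_ic = _get(landmarks, "L_ILIAC_CREST")
    r_ic = _get(landmarks, "R_ILIAC_CREST")
    l_it = _get(landmarks, "L_ISCHIAL_TUB")
    r_it = _get(landmarks, "R_ISCHIAL_TUB")
    mid_ic = 0.5 * (l_ic + r_ic)
    mid_it = 0.5 * (l_it + r_it)
    x_hat = _unit(mid_ic - mid_it, "pelvis x-axis")
    z_raw = r_ic - l_ic
    z_hat = _unit(z_raw - (z_raw @ x_hat) * x_hat, "pelvis z-axis")
    y_hat = np.cross(z_hat, x_hat)
    pelvis = RigidTransform(np.column_stack([x_hat, y_hat, z_hat]), mid_ic)

    gt = _get(landmarks, "GT")
    lat_ep = _get(landmarks, "LAT_EPICONDYLE")
    med_ep = _get(landmarks, "MED_EPICONDYLE")
    f_origin = 0.5 * (lat_ep + med_ep)
    f_y = _unit(gt - f_origin, "femur y-axis")
    femur = _frame_from_axes(f_origin, f_y, lat_ep - f_origin, "femur z-axis")

    lat_mal = _get(landmarks, "LAT_MALLEOLUS")
    med_mal = _get(landmarks, "MED_MALLEOLUS")
    fib = _get(landmarks, "FIB_HEAD")
    ptc = _get(landmarks, "PROX_TIB_CREST")
    t_origin = 0.5 * (lat_mal + med_mal)
    t_y = _unit(0.5 * (fib + ptc) - t_origin, "tibia y-axis")
    tibia = _frame_from_axes(t_origin, t_y, lat_mal - t_origin, "tibia z-axis")

    return {"pelvis": pelvis, "femur": femur, "tibia": tibia}


def build_marker_templates(
    landmarks: dict, frames: dict[str, RigidTransform]
) -> dict[str, dict[str, np.ndarray]]:
    """Express each segment's markers in its anatomical frame.

    Template coordinates are constant per subject: they are the calibration
    marker positions pulled back through the inverse AF pose.
    """
    templates: dict[str, dict[str, np.ndarray]] = {}
    for seg in SEGMENTS:
        inv = frames[seg].inverse()
        templates[seg] = {
            name: inv.apply(_get(landmarks, name)) for name in SEGMENT_MARKERS[seg]
        }
    return templates


@dataclass(frozen=True)
class HjcRegressionModel:
    """Landmark regression for the hip joint centre in the pelvic AF.

    Each of the craniocaudal (x) and lateromedial (z) coordinates is a
    linear function of pelvic width w (distance between the iliac crest
    markers) and pelvic length l (distance between the iliac and ischial
    midpoints): ``coord = c0 + cw * w + cl * l``.  The proximodistal (y)
    coordinate is not regressed; it comes from the greater-trochanter
    height above the posterior pelvic plane.
    """

    x_coeffs: tuple  # (intercept mm, per-mm width, per-mm length)
    z_coeffs: tuple
    residual_rms: tuple = (0.0, 0.0)  # (x, z) training residual RMS, mm
    n_training: int = 0

    def predict(self, width: float, height_length: float) -> tuple[float, float]:
        a0, aw, al = self.x_coeffs
        c0, cw, cl = self.z_coeffs
        return (
            a0 + aw * width + al * height_length,
            c0 + cw * width + cl * height_length,
        )


def fit_hjc_regression(training) -> HjcRegressionModel:
    """Fit the hip-joint-centre regression by ordinary least squares.

    Parameters
    ----------
    training : sequence of (width_mm, length_mm, hjc_in_pelvis)
        One entry per training subject; ``hjc_in_pelvis`` is the reference
        hip joint centre in that subject's pelvic AF (mm).
    """
    rows = list(training)
    if len(rows) < 3:
        raise DegenerateGeometryError(
            f"regression needs >= 3 training subjects, got {len(rows)}"
        )
    W = np.array([r[0] for r in rows], dtype=float)
    L = np.array([r[1] for r in rows], dtype=float)
    H = np.array([np.asarray(r[2], dtype=float).reshape(3) for r in rows])
    A = np.column_stack([np.ones_like(W), W, L])
    if np.linalg.matrix_rank(A) < 3:
        raise DegenerateGeometryError("predictor matrix is rank-deficient")
    coef_x, _, _, _ = np.linalg.lstsq(A, H[:, 0], rcond=None)
    coef_z, _, _, _ = np.linalg.lstsq(A, H[:, 2], rcond=None)
    rms_x = float(np.sqrt(np.mean((A @ coef_x - H[:, 0]) ** 2)))
    rms_z = float(np.sqrt(np.mean((A @ coef_z - H[:, 2]) ** 2)))
    return HjcRegressionModel(
        x_coeffs=tuple(coef_x),
        z_coeffs=tuple(coef_z),
        residual_rms=(rms_x, rms_z),
        n_training=len(rows),
    )


@dataclass(frozen=True)
class JointCentres:
    """Hip and stifle joint centres in the AFs of both adjacent segments (mm)."""

    hjc_in_pelvis: np.ndarray
    hjc_in_femur: np.ndarray
    sjc_in_femur: np.ndarray
    sjc_in_tibia: np.ndarray

    def __post_init__(self):
        for name in ("hjc_in_pelvis", "hjc_in_femur", "sjc_in_femur", "sjc_in_tibia"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise InvalidArgumentError(f"{name} has non-finite components")
            object.__setattr__(self, name, v)


def pelvic_dimensions(landmarks: dict) -> tuple[float, float]:
    """Pelvic width (between iliac crests) and length (iliac midpoint to
    ischial midpoint), mm."""
    l_ic = _get(landmarks, "L_ILIAC_CREST")
    r_ic = _get(landmarks, "R_ILIAC_CREST")
    l_it = _get(landmarks, "L_ISCHIAL_TUB")
    r_it = _get(landmarks, "R_ISCHIAL_TUB")
    width = float(np.linalg.norm(r_ic - l_ic))
    length = float(np.linalg.norm(0.5 * (l_ic + r_ic) - 0.5 * (l_it + r_it)))
    return width, length


def posterior_pelvic_plane(landmarks: dict, frames: dict):
    """Total-least-squares plane through the four pelvic landmarks, with the
    normal oriented dorsally (positive component along the pelvic y-axis)."""
    pts = np.array([_get(landmarks, n) for n in PELVIC_LANDMARKS])
    plane = fit_plane(pts)
    normal = plane.normal
    y_hat = frames["pelvis"].rotation[:, 1]
    if normal @ y_hat < 0:
        normal = -normal
    return plane.point, normal


def predict_joint_centres(
    landmarks: dict, frames: dict[str, RigidTransform], model: HjcRegressionModel
) -> JointCentres:
    """Predict the hip and stifle joint centres from calibration landmarks.

    Hip: x and z in the pelvic AF come from the width/length regression;
    y is minus the (dorsal-positive) distance of the greater trochanter
    from the posterior pelvic plane, placing the centre ventral to the
    plane.  Stifle: the origin of the femoral AF (midpoint of the
    epicondyles), exactly (0, 0, 0) in femoral coordinates.
    """
    width, length = pelvic_dimensions(landmarks)
    x, z = model.predict(width, length)
    point, normal = posterior_pelvic_plane(landmarks, frames)
    gt = _get(landmarks, "GT")
    dist = float(normal @ (gt - point))
    if abs(dist) < 1e-9:
        warnings.warn("GT lies on the posterior pelvic plane; hip y-coordinate is 0")
    # the hip centre sits ventral (distal) to the posterior pelvic plane at
    # trochanter depth, whichever side of the plane the GT marker falls on
    hjc_in_pelvis = np.array([x, -abs(dist), z])

    pelvis, femur, tibia = frames["pelvis"], frames["femur"], frames["tibia"]
    hjc_lab = pelvis.apply(hjc_in_pelvis)
    sjc_lab = femur.translation  # femoral AF origin
    return JointCentres(
        hjc_in_pelvis=hjc_in_pelvis,
        hjc_in_femur=femur.inverse().apply(hjc_lab),
        sjc_in_femur=np.zeros(3),
        sjc_in_tibia=tibia.inverse().apply(sjc_lab),
    )


def reference_joint_centres(
    femoral_head_cloud,
    condyle_cloud,
    frames: dict[str, RigidTransform],
) -> JointCentres:
    """Joint centres from bone-surface point clouds (laboratory frame).

    The hip centre is the centre of the best-fitted sphere to the femoral
    head cloud; the stifle centre is the mid-extent axis point of the
    best-fitted cylinder to the bilateral condyle cloud.  The cylinder
    axis search is seeded with the femoral lateral (z) axis, the expected
    flexion axis direction.
    """
    sphere: SphereFitResult = fit_sphere(femoral_head_cloud)
    cyl: CylinderFitResult = fit_cylinder(
        condyle_cloud, init_axis=frames["femur"].rotation[:, 2]
    )
    hjc_lab = sphere.centre
    sjc_lab = cyl.axis_point
    pelvis, femur, tibia = frames["pelvis"], frames["femur"], frames["tibia"]
    return JointCentres(
        hjc_in_pelvis=pelvis.inverse().apply(hjc_lab),
        hjc_in_femur=femur.inverse().apply(hjc_lab),
        sjc_in_femur=femur.inverse().apply(sjc_lab),
        sjc_in_tibia=tibia.inverse().apply(sjc_lab),
    )


@dataclass
class MultibodyModel:
    """The subject-specific three-segment chain used for tracking.

    Holds the calibration AF poses, per-segment marker templates, the hip
    and stifle centres in both adjacent AFs, per-marker weights and the
    list of markers available in dynamic trials (medial markers excluded).
    """

    frames: dict[str, RigidTransform]
    templates: dict[str, dict[str, np.ndarray]]
    centres: JointCentres
    weights: dict[str, float] = field(default_factory=dict)
    dynamic_markers: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def segment_of(self, marker: str) -> str:
        for seg in SEGMENTS:
            if marker in self.templates[seg]:
                return seg
        raise ConfigurationError(f"marker '{marker}' is assigned to no segment")

    def dynamic_template(self, segment: str):
        """(names, (n,3) local coordinates) of a segment's dynamic markers."""
        names = self.dynamic_markers[segment]
        return names, np.array([self.templates[segment][n] for n in names])

    def with_centres(self, centres: JointCentres) -> "MultibodyModel":
        return MultibodyModel(
            frames=self.frames,
            templates=self.templates,
            centres=centres,
            weights=dict(self.weights),
            dynamic_markers=dict(self.dynamic_markers),
        )

    def with_weights(self, weights: dict) -> "MultibodyModel":
        return MultibodyModel(
            frames=self.frames,
            templates=self.templates,
            centres=self.centres,
            weights={k: float(v) for k, v in weights.items()},
            dynamic_markers=dict(self.dynamic_markers),
        )


def _check_centre_consistency(frames: dict, centres: JointCentres) -> None:
    pelvis, femur, tibia = frames["pelvis"], frames["femur"], frames["tibia"]
    hjc_gap = np.linalg.norm(
        pelvis.apply(centres.hjc_in_pelvis) - femur.apply(centres.hjc_in_femur)
    )
    sjc_gap = np.linalg.norm(
        femur.apply(centres.sjc_in_femur) - tibia.apply(centres.sjc_in_tibia)
    )
    if hjc_gap > _CONSISTENCY_TOL or sjc_gap > _CONSISTENCY_TOL:
        raise ModelValidityError(
            "joint centre expressions disagree at calibration "
            f"(hip gap {hjc_gap:.3g} mm, stifle gap {sjc_gap:.3g} mm)"
        )


def assemble_model(
    frames: dict[str, RigidTransform],
    templates: dict[str, dict[str, np.ndarray]],
    centres: JointCentres,
    weights: dict | None = None,
    dynamic_markers: dict | None = None,
) -> MultibodyModel:
    """Validate and assemble the multibody model.

    Dynamic marker lists default to each segment's markers minus the medial
    calibration-only markers; every segment must retain at least three
    dynamic markers for its pose to be observable.  Weights default to 1.
    """
    if dynamic_markers is None:
        dynamic_markers = {
            seg: tuple(n for n in SEGMENT_MARKERS[seg] if n not in MEDIAL_MARKERS)
            for seg in SEGMENTS
        }
    else:
        dynamic_markers = {seg: tuple(dynamic_markers[seg]) for seg in SEGMENTS}

    for seg in SEGMENTS:
        for name in dynamic_markers[seg]:
            if name not in templates[seg]:
                raise ConfigurationError(
                    f"dynamic marker '{name}' has no template on segment '{seg}'"
                )
        if len(dynamic_markers[seg]) < 3:
            raise ModelValidityError(
                f"segment '{seg}' has {len(dynamic_markers[seg])} dynamic markers; "
                "at least 3 are required to track its pose"
            )

    _check_centre_consistency(frames, centres)

    all_dynamic = [n for seg in SEGMENTS for n in dynamic_markers[seg]]
    if weights is None:
        weights = {n: 1.0 for n in all_dynamic}
    else:
        weights = {n: float(weights.get(n, 1.0)) for n in all_dynamic}
        if any(w < 0 or not np.isfinite(w) for w in weights.values()):
            raise InvalidArgumentError("marker weights must be finite and >= 0")

    return MultibodyModel(
        frames=dict(frames),
        templates={s: {k: np.asarray(v, float).reshape(3) for k, v in templates[s].items()} for s in SEGMENTS},
        centres=centres,
        weights=weights,
        dynamic_markers=dynamic_markers,
    )


def build_model(
    landmarks: dict,
    regression: HjcRegressionModel,
    weights: dict | None = None,
) -> MultibodyModel:
    """One-call calibration: frames, templates, predicted centres, assembly."""
    frames = build_anatomical_frames(landmarks)
    templates = build_marker_templates(landmarks, frames)
    centres = predict_joint_centres(landmarks, frames, regression)
    return assemble_model(frames, templates, centres, weights=weights)
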