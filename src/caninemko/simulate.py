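"""Seeded synthesis of canine treadmill gait with soft tissue artefact.

Because no marker/fluoroscopy dataset is distributable, every estimator
in this toolkit is exercised against a virtual cohort generated here:

* a standing-calibration landmark layout for a medium (~19 kg) dog,
  anisotropically scaled per subject so pelvic width and length vary
  about +/-15 % across the cohort;
* a periodic gait script for treadmill walking at 0.7 m/s — smooth
  Fourier waveforms for the hip and stifle Cardan angles (default
  flexion/extension ranges 30 deg hip, 40 deg stifle; out-of-sagittal
  ranges <= 10 deg) and a small pelvic oscillation;
* a soft-tissue-artefact (STA) model with a per-segment *rigid*
  component (the whole marker cluster translates and rotates relative to
  the bone, phase-locked to the gait cycle) and a per-marker *non-rigid*
  component (independent sinusoidal excursions), plus isotropic
  measurement noise.  Amplitudes follow the thigh > crus > pelvis
  ordering expected from canine skin mobility.

Ground-truth poses are generated by forward kinematics of the subject's
own 12-coordinate chain, so the spherical joint constraints hold exactly
and the true joint angles are read off the generalized coordinates.
All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bodymodel import (
    HjcRegressionModel,
    MultibodyModel,
    SEGMENTS,
    build_anatomical_frames,
    build_marker_templates,
    assemble_model,
    fit_hjc_regression,
    pelvic_dimensions,
    predict_joint_centres,
)
from .errors import InvalidArgumentError
from .geometry import RigidTransform, cardan_zxy_to_rotation, rotation_to_cardan_zxy
from .tracking import MarkerTrajectorySet, TrackingResult, forward_kinematics

__all__ = [
    "BASE_LANDMARKS",
    "GaitScript",
    "StaModel",
    "SyntheticSubject",
    "SyntheticTrial",
    "make_landmarks",
    "make_subject",
    "default_hjc_regression",
    "generate_gait_script",
    "synthesize_trial",
    "synthesize_bone_clouds",
]

#: Standing calibration layout (laboratory frame, mm): x cranial, y up,
#: z lateral-right.  Sized for a ~19 kg medium dog standing on a treadmill.
BASE_LANDMARKS: dict[str, tuple] = {
    "L_ILIAC_CREST": (0.0, 400.0, -40.0),
    "R_ILIAC_CREST": (0.0, 400.0, 40.0),
    "L_ISCHIAL_TUB": (-110.0, 385.0, -35.0),
    "R_ISCHIAL_TUB": (-110.0, 385.0, 35.0),
    "GT": (-95.0, 378.0, 60.0),
    "LAT_EPICONDYLE": (-35.0, 230.0, 58.0),
    "MED_EPICONDYLE": (-35.0, 230.0, 22.0),
    "FIB_HEAD": (-40.0, 222.0, 55.0),
    "PROX_TIB_CREST": (-28.0, 214.0, 40.0),
    "DIST_TIB_CREST": (-55.0, 150.0, 42.0),
    "LAT_MALLEOLUS": (-80.0, 90.0, 58.0),
    "MED_MALLEOLUS": (-80.0, 90.0, 32.0),
    "THIGH_TRACK_1": (-52.0, 322.0, 56.0),
    "THIGH_TRACK_2": (-42.0, 282.0, 58.0),
    "FOOT": (-45.0, 25.0, 48.0),
}

#: anatomical hip centre (femoral head) and stifle centre of the base layout
BASE_TRUE_HJC = np.array([-92.0, 372.0, 38.0])

_SCALE_ANCHOR = np.array([0.0, 400.0, 0.0])

_PHASE_GRID = np.linspace(0.0, 1.0, 2048, endpoint=False)


def _scale_matrix(width_scale: float, length_scale: float) -> np.ndarray:
    return np.diag([length_scale, 0.5 * (length_scale + width_scale), width_scale])


def make_landmarks(
    width_scale: float = 1.0,
    length_scale: float = 1.0,
    placement_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Scaled (and optionally jittered) calibration landmark set.

    Width scaling acts laterally (z), length scaling cranio-caudally (x);
    the vertical dimension follows their mean.  ``placement_sd`` adds
    isotropic Gaussian jitter per landmark to emulate palpation/placement
    variability.
    """
    S = _scale_matrix(width_scale, length_scale)
    if placement_sd > 0 and rng is None:
        raise InvalidArgumentError("placement jitter requires an rng")
    out = {}
    for name, p in BASE_LANDMARKS.items():
        q = _SCALE_ANCHOR + S @ (np.asarray(p) - _SCALE_ANCHOR)
        if placement_sd > 0:
            q = q + rng.normal(0.0, placement_sd, 3)
        out[name] = q
    return out


def true_hip_centre(width_scale: float = 1.0, length_scale: float = 1.0) -> np.ndarray:
    """Laboratory position of the anatomical hip centre for a scaled subject."""
    S = _scale_matrix(width_scale, length_scale)
    return _SCALE_ANCHOR + S @ (BASE_TRUE_HJC - _SCALE_ANCHOR)


def default_hjc_regression(
    n_subjects: int = 24, noise_sd: float = 2.0, seed: int = 20240
) -> HjcRegressionModel:
    """Hip-centre regression fitted to a synthetic training population.

    Twenty-four virtual pelves with width/length scales drawn uniformly in
    [0.85, 1.15] provide (width, length, anatomical hip centre) triples;
    the anatomical centre is perturbed by ``noise_sd`` mm to emulate
    inter-individual shape variability not captured by the two predictors.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_subjects):
        ws, ls = rng.uniform(0.85, 1.15, 2)
        lm = make_landmarks(ws, ls)
        frames = build_anatomical_frames(lm)
        hjc_lab = true_hip_centre(ws, ls) + rng.normal(0.0, noise_sd, 3)
        hjc_pelvis = frames["pelvis"].inverse().apply(hjc_lab)
        rows.append(pelvic_dimensions(lm) + (hjc_pelvis,))
    return fit_hjc_regression(rows)


# ---------------------------------------------------------------------------
# gait script
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitScript:
    """Periodic ground-truth motion over one stride.

    Joint waveforms are sums of sinusoids in gait phase (deviations from
    the standing calibration angles, degrees); the pelvis oscillates
    gently about its calibration pose.  ``harmonics`` entries are
    ``(amplitude, harmonic, phase_rad)``.
    """

    stride_duration: float  # s
    belt_speed: float  # m/s
    hip: tuple  # 3 components, each a tuple of (amp_deg, harmonic, phase)
    stifle: tuple
    pelvis_translation: tuple  # 3 x (amp_mm, harmonic, phase)
    pelvis_rotation: tuple  # 3 x (amp_deg, harmonic, phase)
    foot_lift: float = 30.0  # mm vertical clearance during swing

    def _eval(self, terms, phase: np.ndarray) -> np.ndarray:
        out = np.zeros_like(phase, dtype=float)
        for amp, harm, ph in terms:
            out = out + amp * np.sin(2.0 * np.pi * harm * phase + ph)
        return out

    def joint_waveform(self, joint: str, phase) -> np.ndarray:
        """(n, 3) Cardan deviations for 'hip' or 'stifle' at given phases."""
        phase = np.asarray(phase, dtype=float)
        terms = self.hip if joint == "hip" else self.stifle
        return np.column_stack([self._eval(t, phase) for t in terms])

    def pelvis_waveform(self, phase):
        phase = np.asarray(phase, dtype=float)
        trans = np.column_stack([self._eval([t], phase) for t in self.pelvis_translation])
        rot = np.column_stack([self._eval([t], phase) for t in self.pelvis_rotation])
        return trans, rot

    def component_range(self, joint: str, component: int) -> float:
        """Peak-to-peak range (deg) of one Cardan component over the cycle."""
        return float(np.ptp(self.joint_waveform(joint, _PHASE_GRID)[:, component]))


def generate_gait_script(
    stride_duration: float = 0.7,
    belt_speed: float = 0.7,
    hip_fe_range: float = 30.0,
    stifle_fe_range: float = 40.0,
    seed: int = 0,
) -> GaitScript:
    """Smooth periodic waveforms for treadmill walking.

    Flexion/extension waveforms mix a fundamental and a second harmonic
    and are rescaled so their peak-to-peak range equals the requested
    value exactly; out-of-sagittal components are single low-amplitude
    sinusoids (range <= 10 deg).  The seed perturbs phases and harmonic
    mixing to individualize subjects without changing the ranges.
    """
    if stride_duration <= 0:
        raise InvalidArgumentError("stride duration must be positive")
    rng = np.random.default_rng(seed)

    def fe_terms(target_range: float, base_phase: float):
        mix = 0.25 + 0.1 * rng.random()
        ph1 = base_phase + rng.normal(0.0, 0.15)
        ph2 = ph1 + 1.0 + rng.normal(0.0, 0.2)
        terms = [(1.0, 1, ph1), (mix, 2, ph2)]
        span = np.ptp(sum(a * np.sin(2 * np.pi * h * _PHASE_GRID + p) for a, h, p in terms))
        k = target_range / span
        return tuple((a * k, h, p) for a, h, p in terms)

    def small_term(lo: float, hi: float):
        return ((rng.uniform(lo, hi) / 2.0, int(rng.integers(1, 3)), rng.uniform(0, 2 * np.pi)),)

    hip = (
        fe_terms(hip_fe_range, base_phase=0.3),
        small_term(3.0, 8.0),  # adduction/abduction range 3-8 deg
        small_term(4.0, 10.0),  # internal/external range 4-10 deg
    )
    stifle = (
        fe_terms(stifle_fe_range, base_phase=-0.6),
        small_term(3.0, 8.0),
        small_term(4.0, 10.0),
    )
    pelvis_translation = tuple(
        (amp, harm, rng.uniform(0, 2 * np.pi))
        for amp, harm in [(5.0, 1), (8.0, 2), (3.0, 1)]
    )
    pelvis_rotation = tuple(
        (amp, 1, rng.uniform(0, 2 * np.pi)) for amp in (1.5, 1.0, 1.0)
    )
    return GaitScript(
        stride_duration=float(stride_duration),
        belt_speed=float(belt_speed),
        hip=hip,
        stifle=stifle,
        pelvis_translation=pelvis_translation,
        pelvis_rotation=pelvis_rotation,
    )


# ---------------------------------------------------------------------------
# soft tissue artefact
# ---------------------------------------------------------------------------

#: default rigid-component amplitudes per segment: rotation (deg, about the
#: segment z/x/y) and translation (mm, along segment x/y/z), one gait-locked
#: sinusoid each.  Thigh skin is by far the most mobile.
DEFAULT_RIGID_ROT = {"pelvis": (1.0, 0.5, 0.5), "femur": (6.0, 1.5, 2.0), "tibia": (3.0, 1.0, 1.0)}
DEFAULT_RIGID_TRANS = {"pelvis": (1.5, 1.0, 1.0), "femur": (4.0, 3.0, 1.5), "tibia": (2.0, 1.5, 1.0)}

#: default non-rigid per-marker sinusoid amplitude (mm) by segment
DEFAULT_NONRIGID_AMP = {"pelvis": 0.8, "femur": 2.0, "tibia": 1.0}

DEFAULT_NOISE_SD = 0.3  # mm


@dataclass(frozen=True)
class StaModel:
    """Parametric soft-tissue-artefact generator.

    ``rigid[segment] = (rot_amp(3), rot_phase(3), trans_amp(3),
    trans_phase(3))`` drives a whole-cluster rotation about the cluster
    centroid plus a translation, both expressed in the segment frame and
    phase-locked to the gait cycle (first harmonic).  ``nonrigid[marker]
    = (amp_mm, direction(3) in the segment frame, harmonic, phase)`` adds
    an independent excursion per marker.  ``noise_sd`` is isotropic
    measurement noise in mm.
    """

    rigid: dict = field(default_factory=dict)
    nonrigid: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    @classmethod
    def preset(
        cls,
        name: str = "full",
        seed: int = 0,
        rigid_scale: float = 1.0,
        nonrigid_scale: dict | float = 1.0,
        noise_sd: float = DEFAULT_NOISE_SD,
        markers_by_segment: dict | None = None,
    ) -> "StaModel":
        """Build an artefact model from the default amplitude tables.

        ``name``: 'none' (noise only, zero if noise_sd=0), 'rigid',
        'nonrigid' or 'full'.  ``nonrigid_scale`` may be a scalar or a
        per-segment dict (e.g. ``{'femur': 3.0}`` to triple the thigh
        marker excursions).  Phases and non-rigid directions are drawn
        reproducibly from the seed.
        """
        if name not in ("none", "rigid", "nonrigid", "full"):
            raise InvalidArgumentError(f"unknown STA preset '{name}'")
        rng = np.random.default_rng(seed)
        if markers_by_segment is None:
            from .bodymodel import SEGMENT_MARKERS, MEDIAL_MARKERS

            markers_by_segment = {
                s: tuple(m for m in SEGMENT_MARKERS[s] if m not in MEDIAL_MARKERS)
                for s in SEGMENTS
            }
        rigid = {}
        nonrigid = {}
        for seg in SEGMENTS:
            if name in ("rigid", "full"):
                rigid[seg] = (
                    tuple(rigid_scale * a for a in DEFAULT_RIGID_ROT[seg]),
                    tuple(rng.uniform(0, 2 * np.pi, 3)),
                    tuple(rigid_scale * a for a in DEFAULT_RIGID_TRANS[seg]),
                    tuple(rng.uniform(0, 2 * np.pi, 3)),
                )
            if name in ("nonrigid", "full"):
                scale = (
                    nonrigid_scale.get(seg, 1.0)
                    if isinstance(nonrigid_scale, dict)
                    else nonrigid_scale
                )
                for m in markers_by_segment[seg]:
                    direction = rng.normal(size=3)
                    direction /= np.linalg.norm(direction)
                    nonrigid[m] = (
                        scale * DEFAULT_NONRIGID_AMP[seg],
                        tuple(direction),
                        int(rng.integers(1, 3)),
                        float(rng.uniform(0, 2 * np.pi)),
                    )
        return cls(rigid=rigid, nonrigid=nonrigid, noise_sd=noise_sd, seed=seed)

    @classmethod
    def none(cls) -> "StaModel":
        """Zero artefact, zero noise: markers follow the bones exactly."""
        return cls(rigid={}, nonrigid={}, noise_sd=0.0, seed=0)


# ---------------------------------------------------------------------------
# subjects and trials
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSubject:
    """A virtual dog: calibration landmarks, the multibody model built from
    them, and the anatomical scales used."""

    landmarks: dict
    model: MultibodyModel
    width_scale: float
    length_scale: float
    seed: int


def make_subject(
    seed: int,
    regression: HjcRegressionModel | None = None,
    placement_sd: float = 1.5,
) -> SyntheticSubject:
    """One virtual cohort member.

    Pelvic width and length scales are drawn uniformly in [0.85, 1.15];
    landmark placement jitter (default 1.5 mm SD) emulates palpation
    variability.  The model's joint centres come from the landmark
    pipeline (regression + trochanter height + epicondyle midpoint) and
    define this subject's ground-truth chain.
    """
    rng = np.random.default_rng(seed)
    ws, ls = rng.uniform(0.85, 1.15, 2)
    lm = make_landmarks(ws, ls, placement_sd=placement_sd, rng=rng)
    if regression is None:
        regression = default_hjc_regression()
    frames = build_anatomical_frames(lm)
    templates = build_marker_templates(lm, frames)
    centres = predict_joint_centres(lm, frames, regression)
    model = assemble_model(frames, templates, centres)
    return SyntheticSubject(landmarks=lm, model=model, width_scale=ws, length_scale=ls, seed=seed)


@dataclass
class SyntheticTrial:
    """A synthetic walking trial with full ground truth."""

    trajectories: MarkerTrajectorySet  # dynamic markers + FOOT, artefact applied
    truth: TrackingResult  # artefact-free segment poses
    truth_dof: np.ndarray  # (n_frames, 12) generalized coordinates
    truth_hip: np.ndarray  # (n_frames, 3) Cardan deg
    truth_stifle: np.ndarray
    contacts: np.ndarray  # paw-contact frame indices
    model: MultibodyModel
    script: GaitScript
    sta: StaModel


def synthesize_trial(
    model: MultibodyModel,
    script: GaitScript,
    sta: StaModel,
    n_cycles: int = 3,
    rate_hz: float = 100.0,
    seed: int = 0,
    foot_calibration=None,
) -> SyntheticTrial:
    """Generate one treadmill trial.

    Ground-truth poses are forward kinematics of the model's own chain
    driven by the gait script; measured markers add the segment-rigid
    artefact (about the marker-cluster centroid), the per-marker
    non-rigid artefact and Gaussian noise.  The foot marker oscillates
    fore–aft with the belt so its cranial-most excursion marks paw
    contact at every integer cycle.
    """
    if n_cycles < 1:
        raise InvalidArgumentError("need at least one gait cycle")
    if rate_hz <= 0:
        raise InvalidArgumentError("sampling rate must be positive")
    rng = np.random.default_rng(seed)
    T = script.stride_duration
    # record a 10 % stride lead-in/out so every paw contact (including the
    # first and last) is an interior event detectable from the foot marker
    lead = 0.1 * T
    n = int(round((n_cycles * T + 2 * lead) * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    phase = (t - lead) / T

    frames_cal = model.frames
    cal_pelvis = frames_cal["pelvis"]
    hip_cal = rotation_to_cardan_zxy(
        cal_pelvis.rotation.T @ frames_cal["femur"].rotation
    )
    stifle_cal = rotation_to_cardan_zxy(
        frames_cal["femur"].rotation.T @ frames_cal["tibia"].rotation
    )
    pelvis_cal_ang = rotation_to_cardan_zxy(cal_pelvis.rotation)

    trans_osc, rot_osc = script.pelvis_waveform(phase)
    hip_wave = script.joint_waveform("hip", phase)
    stifle_wave = script.joint_waveform("stifle", phase)

    dof = np.empty((n, 12))
    dof[:, 0:3] = cal_pelvis.translation + trans_osc
    dof[:, 3:6] = pelvis_cal_ang + rot_osc
    dof[:, 6:9] = hip_cal + hip_wave
    dof[:, 9:12] = stifle_cal + stifle_wave

    rotations = {s: np.empty((n, 3, 3)) for s in SEGMENTS}
    translations = {s: np.empty((n, 3)) for s in SEGMENTS}
    for k in range(n):
        poses = forward_kinematics(dof[k], model.centres)
        for seg in SEGMENTS:
            rotations[seg][k], translations[seg][k] = poses[seg]

    marker_names: list[str] = []
    positions = []
    for seg in SEGMENTS:
        names, template = model.dynamic_template(seg)
        true_pos = np.einsum("kij,mj->kmi", rotations[seg], template) + translations[seg][:, None, :]
        meas = true_pos.copy()
        if seg in sta.rigid:
            rot_amp, rot_ph, trans_amp, trans_ph = sta.rigid[seg]
            ang = np.asarray(rot_amp) * np.sin(
                2 * np.pi * phase[:, None] + np.asarray(rot_ph)
            )
            d_local = np.asarray(trans_amp) * np.sin(
                2 * np.pi * phase[:, None] + np.asarray(trans_ph)
            )
            centroid = meas.mean(axis=1)
            for k in range(n):
                R_seg = rotations[seg][k]
                R_art = R_seg @ cardan_zxy_to_rotation(ang[k]) @ R_seg.T
                meas[k] = centroid[k] + (meas[k] - centroid[k]) @ R_art.T + R_seg @ d_local[k]
        for m, name in enumerate(names):
            if name in sta.nonrigid:
                amp, direction, harm, ph = sta.nonrigid[name]
                dir_lab = np.einsum("kij,j->ki", rotations[seg], np.asarray(direction))
                meas[:, m] += amp * np.sin(2 * np.pi * harm * phase + ph)[:, None] * dir_lab
        marker_names.extend(names)
        positions.append(meas)

    # foot marker: fore-aft excursion of half the stride length, with a
    # vertical swing-phase lift; cranial-most point = paw contact
    foot_cal = (
        np.asarray(foot_calibration, dtype=float)
        if foot_calibration is not None
        else np.asarray(BASE_LANDMARKS["FOOT"], dtype=float)
    )
    half_stride = 0.5 * script.belt_speed * 1000.0 * T
    foot = np.tile(foot_cal, (n, 1))
    foot[:, 0] += half_stride * np.cos(2 * np.pi * phase)
    foot[:, 1] += script.foot_lift * np.clip(np.sin(2 * np.pi * phase + np.pi), 0, None) ** 2
    marker_names.append("FOOT")
    positions.append(foot[:, None, :])

    pos = np.concatenate(positions, axis=1)
    if sta.noise_sd > 0:
        pos = pos + rng.normal(0.0, sta.noise_sd, pos.shape)

    traj = MarkerTrajectorySet(
        rate=rate_hz,
        markers=tuple(marker_names),
        positions=pos,
        visible=np.ones(pos.shape[:2], dtype=bool),
    )
    truth = TrackingResult(
        method="truth",
        rate=rate_hz,
        rotations=rotations,
        translations=translations,
        residual_rms=np.zeros(n),
        frame_valid=np.ones(n, dtype=bool),
        converged=np.ones(n, dtype=bool),
        iterations=np.zeros(n, dtype=int),
        model=model,
    )
    contacts = np.round((np.arange(n_cycles + 1) * T + lead) * rate_hz).astype(int)
    contacts = contacts[contacts < n]
    return SyntheticTrial(
        trajectories=traj,
        truth=truth,
        truth_dof=dof,
        truth_hip=dof[:, 6:9].copy(),
        truth_stifle=dof[:, 9:12].copy(),
        contacts=contacts,
        model=model,
        script=script,
        sta=sta,
    )


def synthesize_bone_clouds(
    true_hjc,
    sjc_axis_point,
    sjc_axis_direction,
    head_radius: float = 11.0,
    condyle_radius: float = 9.0,
    condyle_half_span: float = 16.0,
    n_head: int = 800,
    n_condyle: int = 800,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Bone-like point clouds for the reference joint-centre fits.

    The femoral head is a spherical cap (cone half-angle 70 deg) about
    ``true_hjc``; the condyles are two partial cylindrical bands about the
    stifle flexion axis, one per condyle, spanning 180 deg of arc.
    Returns ``(femoral_head_cloud, condyle_cloud)`` as (n, 3) arrays.
    """
    if head_radius <= 0 or condyle_radius <= 0:
        raise InvalidArgumentError("radii must be positive")
    if n_head < 4 or n_condyle < 6:
        raise InvalidArgumentError("cloud sampling is too sparse")
    rng = np.random.default_rng(seed)
    c = np.asarray(true_hjc, dtype=float).reshape(3)

    # spherical cap about the medially directed neck axis
    cap_axis = np.array([0.0, 0.3, -1.0])
    cap_axis /= np.linalg.norm(cap_axis)
    u = np.cross(cap_axis, [1.0, 0.0, 0.0])
    u /= np.linalg.norm(u)
    v = np.cross(cap_axis, u)
    cos_min = np.cos(np.radians(70.0))
    ct = rng.uniform(cos_min, 1.0, n_head)
    st = np.sqrt(1.0 - ct**2)
    az = rng.uniform(0, 2 * np.pi, n_head)
    dirs = ct[:, None] * cap_axis + st[:, None] * (np.cos(az)[:, None] * u + np.sin(az)[:, None] * v)
    head = c + head_radius * dirs

    a = np.asarray(sjc_axis_point, dtype=float).reshape(3)
    d = np.asarray(sjc_axis_direction, dtype=float).reshape(3)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise InvalidArgumentError("stifle axis direction must be non-zero")
    d = d / nd
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    cu = np.cross(d, ref)
    cu /= np.linalg.norm(cu)
    cv = np.cross(d, cu)
    half = n_condyle // 2
    parts = []
    for smin, smax, count in (
        (-condyle_half_span, -0.25 * condyle_half_span, half),
        (0.25 * condyle_half_span, condyle_half_span, n_condyle - half),
    ):
        s = rng.uniform(smin, smax, count)
        th = rng.uniform(-np.pi / 2, np.pi / 2, count)  # caudal half-arc
        parts.append(
            a
            + s[:, None] * d
            + condyle_radius * (np.cos(th)[:, None] * cu + np.sin(th)[:, None] * cv)
        )
    condyles = np.vstack(parts)

    if noise_sd > 0:
        head = head + rng.normal(0.0, noise_sd, head.shape)
        condyles = condyles + rng.normal(0.0, noise_sd, condyles.shape)
    return head, condyles
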