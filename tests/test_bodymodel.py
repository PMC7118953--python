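"""Anatomical frames, marker templates, joint-centre prediction and
model assembly."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from caninemko.bodymodel import (
    MEDIAL_MARKERS,
    SEGMENTS,
    assemble_model,
    build_anatomical_frames,
    build_marker_templates,
    fit_hjc_regression,
    pelvic_dimensions,
    predict_joint_centres,
    reference_joint_centres,
)
from caninemko.errors import (
    DegenerateGeometryError,
    MissingLandmarkError,
    ModelValidityError,
)
from caninemko.geometry import RigidTransform
from caninemko.bodymodel import HjcRegressionModel
from caninemko.simulate import make_landmarks, synthesize_bone_clouds


def rigid_move(landmarks, R, t):
    return {k: R @ v + t for k, v in landmarks.items()}


class TestAnatomicalFrames:
    def test_canonical_layout_gives_identity_rotations(self, canonical_landmarks):
        frames = build_anatomical_frames(canonical_landmarks)
        for seg in SEGMENTS:
            assert np.allclose(frames[seg].rotation, np.eye(3), atol=1e-12), seg
        assert np.allclose(frames["pelvis"].translation, [0, 0, 0])
        assert np.allclose(frames["femur"].translation, [-20, -80, 0])

    def test_rotations_proper_and_orthonormal(self, subject):
        frames = build_anatomical_frames(subject.landmarks)
        for seg in SEGMENTS:
            R = frames[seg].rotation
            assert np.allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(R) - 1) < 1e-9

    def test_equivariance_under_lab_motion(self, subject):
        R = Rotation.from_euler("zxy", [30, 10, -20], degrees=True).as_matrix()
        t = np.array([100.0, -50.0, 30.0])
        f0 = build_anatomical_frames(subject.landmarks)
        f1 = build_anatomical_frames(rigid_move(subject.landmarks, R, t))
        move = RigidTransform(R, t)
        for seg in SEGMENTS:
            expected = move @ f0[seg]
            assert np.allclose(f1[seg].rotation, expected.rotation, atol=1e-9)
            assert np.allclose(f1[seg].translation, expected.translation, atol=1e-9)

    def test_missing_landmark_is_named(self, canonical_landmarks):
        del canonical_landmarks["GT"]
        with pytest.raises(MissingLandmarkError, match="GT"):
            build_anatomical_frames(canonical_landmarks)


class TestMarkerTemplates:
    def test_round_trip_through_frame_pose(self, subject):
        frames = build_anatomical_frames(subject.landmarks)
        templates = build_marker_templates(subject.landmarks, frames)
        for seg in SEGMENTS:
            for name, local in templates[seg].items():
                assert np.allclose(
                    frames[seg].apply(local), subject.landmarks[name], atol=1e-10
                )

    def test_origin_marker_maps_to_zero(self, canonical_landmarks):
        # femoral AF origin is the epicondyle midpoint; place a landmark there
        frames = build_anatomical_frames(canonical_landmarks)
        templates = build_marker_templates(canonical_landmarks, frames)
        mid = 0.5 * (
            canonical_landmarks["LAT_EPICONDYLE"] + canonical_landmarks["MED_EPICONDYLE"]
        )
        assert np.allclose(frames["femur"].inverse().apply(mid), [0, 0, 0], atol=1e-12)
        # and epicondyles are symmetric about it in the template
        assert np.allclose(
            templates["femur"]["LAT_EPICONDYLE"] + templates["femur"]["MED_EPICONDYLE"],
            [0, 0, 0],
            atol=1e-10,
        )

    def test_templates_invariant_under_lab_motion(self, subject):
        R = Rotation.from_euler("zxy", [-15, 25, 40], degrees=True).as_matrix()
        t = np.array([-70.0, 20.0, 110.0])
        f0 = build_anatomical_frames(subject.landmarks)
        t0 = build_marker_templates(subject.landmarks, f0)
        moved = rigid_move(subject.landmarks, R, t)
        t1 = build_marker_templates(moved, build_anatomical_frames(moved))
        for seg in SEGMENTS:
            for name in t0[seg]:
                assert np.allclose(t0[seg][name], t1[seg][name], atol=1e-9)


class TestHjcRegression:
    def exact_rows(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n):
            w = rng.uniform(60, 100)
            l = rng.uniform(90, 130)
            x = -30 - 0.5 * w - 0.3 * l
            z = -5 + 0.1 * w
            rows.append((w, l, np.array([x, rng.normal(-30, 5), z])))
        return rows

    def test_noiseless_recovery(self):
        model = fit_hjc_regression(self.exact_rows())
        assert np.allclose(model.x_coeffs, (-30, -0.5, -0.3), atol=1e-9)
        assert np.allclose(model.z_coeffs, (-5, 0.1, 0.0), atol=1e-9)
        assert max(model.residual_rms) < 1e-9

    def test_prediction_from_fitted_equation(self):
        model = fit_hjc_regression(self.exact_rows())
        x, z = model.predict(40.0, 100.0)
        assert abs(x - (-80.0)) < 1e-9
        assert abs(z - (-1.0)) < 1e-9

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(24):
            w = rng.uniform(60, 100)
            l = rng.uniform(90, 130)
            hjc = np.array([-30 - 0.5 * w - 0.3 * l, -30.0, -5 + 0.1 * w])
            rows.append((w, l, hjc + rng.normal(0, 2, 3)))
        model = fit_hjc_regression(rows)
        A = np.array([[1.0, r[0], r[1]] for r in rows])
        bx = np.array([r[2][0] for r in rows])
        bz = np.array([r[2][2] for r in rows])
        cx = np.linalg.solve(A.T @ A, A.T @ bx)
        cz = np.linalg.solve(A.T @ A, A.T @ bz)
        assert np.allclose(model.x_coeffs, cx, atol=1e-8)
        assert np.allclose(model.z_coeffs, cz, atol=1e-8)

    def test_coefficient_rmse_shrinks_with_n(self):
        def coef_err(n, seed):
            rng = np.random.default_rng(seed)
            rows = []
            for _ in range(n):
                w = rng.uniform(60, 100)
                l = rng.uniform(90, 130)
                hjc = np.array([-30 - 0.5 * w - 0.3 * l, -30.0, -5 + 0.1 * w])
                rows.append((w, l, hjc + rng.normal(0, 2, 3)))
            m = fit_hjc_regression(rows)
            return np.linalg.norm(np.array(m.x_coeffs) - (-30, -0.5, -0.3))

        small = np.mean([coef_err(24, s) for s in range(10)])
        large = np.mean([coef_err(240, 100 + s) for s in range(10)])
        assert large < small

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_hjc_regression(self.exact_rows(n=2))

    def test_rank_deficient_predictors_rejected(self):
        rows = [(80.0, 100.0, np.zeros(3)), (80.0, 100.0, np.zeros(3)), (80.0, 100.0, np.zeros(3))]
        with pytest.raises(DegenerateGeometryError):
            fit_hjc_regression(rows)


class TestPredictJointCentres:
    def test_stifle_centre_is_femoral_origin(self, subject, regression):
        frames = build_anatomical_frames(subject.landmarks)
        centres = predict_joint_centres(subject.landmarks, frames, regression)
        assert np.allclose(centres.sjc_in_femur, [0, 0, 0])

    def test_zero_regression_isolates_trochanter_height_rule(self, canonical_landmarks):
        # move GT to 25 mm from the (flat) pelvic plane
        lm = dict(canonical_landmarks)
        lm["GT"] = np.array([-20.0, -25.0, 0.0])
        frames = build_anatomical_frames(lm)
        zero = HjcRegressionModel(x_coeffs=(0, 0, 0), z_coeffs=(0, 0, 0))
        centres = predict_joint_centres(lm, frames, zero)
        assert np.allclose(centres.hjc_in_pelvis, [0, -25, 0], atol=1e-9)

    def test_regression_coordinates_feed_through(self, canonical_landmarks):
        lm = dict(canonical_landmarks)
        # canonical pelvis: width 40, length 50.xx; use the known-model coefficients
        model = HjcRegressionModel(x_coeffs=(-30, -0.5, -0.3), z_coeffs=(-5, 0.1, 0))
        frames = build_anatomical_frames(lm)
        w, l = pelvic_dimensions(lm)
        centres = predict_joint_centres(lm, frames, model)
        assert abs(centres.hjc_in_pelvis[0] - (-30 - 0.5 * w - 0.3 * l)) < 1e-9
        assert abs(centres.hjc_in_pelvis[2] - (-5 + 0.1 * w)) < 1e-9

    def test_dual_expression_consistency(self, subject, regression):
        frames = build_anatomical_frames(subject.landmarks)
        c = predict_joint_centres(subject.landmarks, frames, regression)
        assert np.allclose(
            frames["pelvis"].apply(c.hjc_in_pelvis),
            frames["femur"].apply(c.hjc_in_femur),
            atol=1e-9,
        )
        assert np.allclose(
            frames["femur"].apply(c.sjc_in_femur),
            frames["tibia"].apply(c.sjc_in_tibia),
            atol=1e-9,
        )


class TestReferenceJointCentres:
    def test_recovers_generating_centres(self, subject):
        frames = build_anatomical_frames(subject.landmarks)
        hjc_lab = np.array([-90.0, 370.0, 35.0])
        sjc_lab = frames["femur"].translation
        axis = frames["femur"].rotation[:, 2]
        head, condyles = synthesize_bone_clouds(hjc_lab, sjc_lab, axis, seed=3)
        c = reference_joint_centres(head, condyles, frames)
        assert np.allclose(frames["pelvis"].apply(c.hjc_in_pelvis), hjc_lab, atol=1e-6)
        assert np.linalg.norm(frames["femur"].apply(c.sjc_in_femur) - sjc_lab) < 0.5
        # dual expression consistency
        assert np.allclose(
            frames["pelvis"].apply(c.hjc_in_pelvis),
            frames["femur"].apply(c.hjc_in_femur),
            atol=1e-9,
        )


class TestAssembleModel:
    def test_dynamic_marker_sets(self, subject):
        model = subject.model
        assert set(model.dynamic_markers["pelvis"]) == {
            "L_ILIAC_CREST", "R_ILIAC_CREST", "L_ISCHIAL_TUB", "R_ISCHIAL_TUB",
        }
        assert set(model.dynamic_markers["femur"]) == {
            "GT", "LAT_EPICONDYLE", "THIGH_TRACK_1", "THIGH_TRACK_2",
        }
        assert set(model.dynamic_markers["tibia"]) == {
            "FIB_HEAD", "PROX_TIB_CREST", "DIST_TIB_CREST", "LAT_MALLEOLUS",
        }
        for seg in SEGMENTS:
            assert not set(model.dynamic_markers[seg]) & set(MEDIAL_MARKERS)

    def test_default_weights_are_one(self, subject):
        assert all(w == 1.0 for w in subject.model.weights.values())

    def test_too_few_dynamic_markers_rejected(self, subject):
        model = subject.model
        dyn = dict(model.dynamic_markers)
        dyn["femur"] = ("GT", "LAT_EPICONDYLE")  # tracking markers removed
        with pytest.raises(ModelValidityError):
            assemble_model(model.frames, model.templates, model.centres, dynamic_markers=dyn)
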