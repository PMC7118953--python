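"""Shared fixtures: canonical landmark sets, a virtual subject, and the
brute-force registration oracle used to cross-check the closed-form
Procrustes solution."""

import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from caninemko.simulate import default_hjc_regression, make_subject


@pytest.fixture(scope="session")
def regression():
    return default_hjc_regression()


@pytest.fixture(scope="session")
def subject(regression):
    return make_subject(1, regression=regression)


@pytest.fixture()
def canonical_landmarks():
    """Axis-aligned calibration: every anatomical frame has identity rotation
    (x cranial, y proximal, z lateral by construction)."""
    return {
        "L_ILIAC_CREST": np.array([0.0, 0.0, -20.0]),
        "R_ILIAC_CREST": np.array([0.0, 0.0, 20.0]),
        "L_ISCHIAL_TUB": np.array([-50.0, 0.0, -18.0]),
        "R_ISCHIAL_TUB": np.array([-50.0, 0.0, 18.0]),
        "GT": np.array([-20.0, -20.0, 0.0]),
        "LAT_EPICONDYLE": np.array([-20.0, -80.0, 15.0]),
        "MED_EPICONDYLE": np.array([-20.0, -80.0, -15.0]),
        "THIGH_TRACK_1": np.array([-10.0, -40.0, 10.0]),
        "THIGH_TRACK_2": np.array([-5.0, -60.0, 12.0]),
        "FIB_HEAD": np.array([-15.0, -85.0, 8.0]),
        "PROX_TIB_CREST": np.array([-25.0, -85.0, -8.0]),
        "DIST_TIB_CREST": np.array([-22.0, -120.0, 5.0]),
        "LAT_MALLEOLUS": np.array([-20.0, -160.0, 10.0]),
        "MED_MALLEOLUS": np.array([-20.0, -160.0, -10.0]),
        "FOOT": np.array([-10.0, -175.0, 0.0]),
    }


def brute_force_rigid_fit(template, observed, weights, n_starts=20, seed=0):
    """Multi-start nonlinear minimizer of the weighted registration cost,
    independent of the closed-form SVD path.  Parameterizes the rotation as
    a rotation vector and returns (R, t, cost) of the best local optimum."""
    template = np.asarray(template, float)
    observed = np.asarray(observed, float)
    w = np.sqrt(np.asarray(weights, float))[:, None]
    rng = np.random.default_rng(seed)

    def resid(x):
        R = Rotation.from_rotvec(x[:3]).as_matrix()
        return (w * (template @ R.T + x[3:] - observed)).ravel()

    best = None
    t0 = observed.mean(axis=0) - template.mean(axis=0)
    starts = [np.concatenate([np.zeros(3), t0])]
    for _ in range(n_starts - 1):
        starts.append(
            np.concatenate([rng.uniform(-np.pi, np.pi, 3), t0 + rng.normal(0, 20, 3)])
        )
    for x0 in starts:
        sol = least_squares(resid, x0, xtol=1e-14, ftol=1e-14, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol
    R = Rotation.from_rotvec(best.x[:3]).as_matrix()
    return R, best.x[3:], 2.0 * best.cost  # least_squares cost = 0.5 * sum r^2


@pytest.fixture(scope="session")
def rigid_fit_oracle():
    return brute_force_rigid_fit


def weighted_cost(template, observed, weights, R, t):
    d = np.asarray(template) @ R.T + t - np.asarray(observed)
    return float(np.sum(np.asarray(weights) * (d**2).sum(axis=1)))


@pytest.fixture(scope="session")
def cost_fn():
    return weighted_cost
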