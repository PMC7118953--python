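"""Joint angles, gait-cycle handling and waveform agreement statistics.

Joint rotations are reported as Cardan z-x-y angles (flexion/extension,
adduction/abduction, internal/external rotation, degrees): the hip from
the pelvis-to-femur relative rotation and the stifle from femur-to-tibia.
Gait cycles run between successive paw contacts of the instrumented limb
and waveforms are resampled to 101 points over 0–100 % of the cycle.

Agreement between an estimated and a reference waveform is summarized the
way method-comparison studies do: Bland–Altman bias and limits-of-
agreement half-width, the coefficient of determination from ordinary
regression, and the root-mean-square difference.  Paired between-method
comparisons gate the test choice on Shapiro–Wilk normality of the
differences: paired t when normal, Wilcoxon signed-rank otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .errors import GimbalLockError, InvalidArgumentError, NoEventError
from .geometry import rotation_to_cardan_zxy
from .tracking import TrackingResult

__all__ = [
    "JointAngleSeries",
    "AgreementReport",
    "PairedComparison",
    "compute_joint_angles",
    "detect_paw_contacts",
    "normalize_to_gait_cycle",
    "agreement_stats",
    "paired_compare",
]

ANGLE_COMPONENTS = ("flexion_extension", "adduction_abduction", "internal_external")
N_CYCLE_SAMPLES = 101
ALPHA = 0.05


@dataclass
class JointAngleSeries:
    """Hip and stifle Cardan z-x-y angles per tracked frame (degrees).

    ``hip``/``stifle`` are (n_frames, 3) arrays ordered
    flexion/extension, adduction/abduction, internal/external rotation;
    frames without a valid pose hold NaN.
    """

    rate: float
    hip: np.ndarray
    stifle: np.ndarray
    valid: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.hip.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate


def compute_joint_angles(result: TrackingResult) -> JointAngleSeries:
    """Hip and stifle joint angles from tracked segment poses.

    A gimbal-lock failure in the decomposition is re-raised with the
    offending frame index attached.
    """
    n = result.n_frames
    hip = np.full((n, 3), np.nan)
    stifle = np.full((n, 3), np.nan)
    for k in np.nonzero(result.frame_valid)[0]:
        R_p = result.rotations["pelvis"][k]
        R_f = result.rotations["femur"][k]
        R_t = result.rotations["tibia"][k]
        try:
            hip[k] = rotation_to_cardan_zxy(R_p.T @ R_f)
            stifle[k] = rotation_to_cardan_zxy(R_f.T @ R_t)
        except GimbalLockError as exc:
            raise GimbalLockError(f"frame {k}: {exc}") from exc
    return JointAngleSeries(
        rate=result.rate, hip=hip, stifle=stifle, valid=result.frame_valid.copy()
    )


def detect_paw_contacts(
    foot_trajectory,
    rate: float,
    direction_of_travel=(1.0, 0.0, 0.0),
    cutoff_hz: float = 6.0,
) -> np.ndarray:
    """Paw-contact frames from the dorsal foot marker.

    On a treadmill the foot reaches its cranial-most excursion at touch-
    down, so contact is taken as the downward zero-crossing of the foot
    marker's fore–aft velocity.  The fore–aft coordinate is low-pass
    filtered (2nd-order Butterworth, zero-phase, 6 Hz default) before
    differentiation.

    Returns strictly increasing frame indices; raises
    :class:`NoEventError` when no crossing exists (e.g. a stationary
    marker).
    """
    pos = np.asarray(foot_trajectory, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        raise InvalidArgumentError("foot trajectory must be (n_frames, 3)")
    d = np.asarray(direction_of_travel, dtype=float).reshape(3)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise InvalidArgumentError("direction of travel must be non-zero")
    x = pos @ (d / nd)
    if x.shape[0] < 7:
        raise NoEventError("trajectory too short for event detection")

    nyq = rate / 2.0
    if cutoff_hz < nyq:
        b, a = signal.butter(2, cutoff_hz / nyq)
        x = signal.filtfilt(b, a, x)
    v = np.gradient(x) * rate
    # require a meaningful excursion so numerical jitter on a stationary
    # marker does not fake events
    if np.ptp(x) < 1.0:  # mm
        raise NoEventError("no fore-aft excursion: marker appears stationary")
    crossings = np.nonzero((v[:-1] > 0) & (v[1:] <= 0))[0]
    if crossings.size == 0:
        raise NoEventError("no downward velocity zero-crossing found")
    # refine to the nearer sample of the crossing interval
    idx = np.where(np.abs(v[crossings]) <= np.abs(v[crossings + 1]), crossings, crossings + 1)
    return np.unique(idx)


def normalize_to_gait_cycle(series, contacts, min_frames: int = 10) -> list:
    """Resample a per-frame series onto 101 points per gait cycle.

    ``series`` is (n_frames,) or (n_frames, m); ``contacts`` are the
    successive paw-contact frame indices.  Each cycle [c_k, c_{k+1}] is
    linearly interpolated onto 101 evenly spaced points (0–100 % of the
    cycle, endpoints included).  Cycles shorter than ``min_frames`` frames
    are rejected with a warning.
    """
    y = np.asarray(series, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    contacts = np.asarray(contacts, dtype=int)
    if contacts.size < 2:
        raise InvalidArgumentError("need at least 2 contacts to delimit a cycle")
    out = []
    for c0, c1 in zip(contacts[:-1], contacts[1:]):
        if c1 - c0 < min_frames:
            warnings.warn(f"cycle {c0}-{c1} shorter than {min_frames} frames; rejected")
            continue
        if c1 >= y.shape[0]:
            raise InvalidArgumentError(f"contact frame {c1} beyond series length {y.shape[0]}")
        t = np.arange(c0, c1 + 1, dtype=float)
        tq = np.linspace(c0, c1, N_CYCLE_SAMPLES)
        wave = np.column_stack([np.interp(tq, t, y[c0 : c1 + 1, j]) for j in range(y.shape[1])])
        out.append(wave[:, 0] if squeeze else wave)
    return out


@dataclass(frozen=True)
class AgreementReport:
    """Bland–Altman bias and CI (limits-of-agreement half-width), R² from
    ordinary regression of test on reference, and RMSD — all in the units
    of the input waveforms (degrees for joint angles)."""

    bias: float
    ci: float
    r_squared: float
    rmsd: float
    n: int


def agreement_stats(test_waveform, reference_waveform, ci_mode: str = "loa") -> AgreementReport:
    """Agreement between an estimated and a reference waveform.

    ``d = test - reference``; bias = mean(d); ci = 1.96·SD(d) (the
    half-width of the 95 % limits of agreement) or, with
    ``ci_mode='bias'``, the 95 % confidence half-width of the bias itself
    (1.96·SD/√n); R² from ordinary least-squares regression of test on
    reference; RMSD = √mean(d²).
    """
    t = np.asarray(test_waveform, dtype=float).ravel()
    r = np.asarray(reference_waveform, dtype=float).ravel()
    if t.shape != r.shape:
        raise InvalidArgumentError("waveforms must have equal length")
    if t.size < 2:
        raise InvalidArgumentError("need at least 2 samples")
    d = t - r
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if ci_mode == "loa":
        ci = 1.96 * sd
    elif ci_mode == "bias":
        ci = 1.96 * sd / np.sqrt(d.size)
    else:
        raise InvalidArgumentError(f"unknown ci_mode '{ci_mode}'")
    rmsd = float(np.sqrt(np.mean(d**2)))
    if np.ptp(r) == 0 or np.ptp(t) == 0:
        r2 = 1.0 if np.allclose(t - t.mean(), r - r.mean()) else 0.0
    else:
        r2 = float(stats.pearsonr(t, r).statistic ** 2)
    return AgreementReport(bias=bias, ci=float(ci), r_squared=r2, rmsd=rmsd, n=int(d.size))


@dataclass(frozen=True)
class PairedComparison:
    """Outcome of a normality-gated paired comparison at alpha = 0.05."""

    differences: np.ndarray
    normality_p: float
    test_used: str  # 'paired-t' | 'wilcoxon' | 'degenerate'
    statistic: float
    p_value: float
    significant: bool


def paired_compare(a, b, alpha: float = ALPHA) -> PairedComparison:
    """Paired comparison of per-subject values.

    The Shapiro–Wilk test on the paired differences (at the same alpha)
    selects the test: paired t when normality is not rejected, Wilcoxon
    signed-rank otherwise.  All-zero differences yield a degenerate
    result (p = 1, flagged, not significant).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 3:
        raise InvalidArgumentError("paired samples must have equal length >= 3")
    d = a - b
    if np.allclose(d, 0.0):
        return PairedComparison(
            differences=d, normality_p=1.0, test_used="degenerate",
            statistic=0.0, p_value=1.0, significant=False,
        )
    sw = stats.shapiro(d)
    if sw.pvalue >= alpha:
        res = stats.ttest_rel(a, b)
        test_used = "paired-t"
    else:
        res = stats.wilcoxon(a, b)
        test_used = "wilcoxon"
    return PairedComparison(
        differences=d,
        normality_p=float(sw.pvalue),
        test_used=test_used,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )
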