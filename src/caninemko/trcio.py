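"""File formats: TRC marker trajectories, CSV tables, YAML models, point clouds.

TRC (tab-separated, five header rows, mm) is the interchange dialect for
marker data; blank coordinate cells mark invisible samples.  Marker CSVs
are accepted in wide form (``frame, time, M_x, M_y, M_z, ...``) or long
form (``frame, marker, x, y, z``).  Models round-trip through YAML with
floats fixed to 12 significant digits so repeated writes are
byte-stable.  All writers emit deterministic output for identical inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
import warnings

import numpy as np
import pandas as pd
import yaml

from .bodymodel import (
    HjcRegressionModel,
    JointCentres,
    MultibodyModel,
    SEGMENTS,
    assemble_model,
)
from .errors import InvalidArgumentError, ParseError
from .geometry import RigidTransform
from .tracking import MarkerTrajectorySet, TrackingResult

__all__ = [
    "read_trc",
    "write_trc",
    "read_markers_csv",
    "save_model",
    "load_model",
    "save_regression",
    "load_regression",
    "write_poses_csv",
    "read_poses_csv",
    "write_waveforms_csv",
    "read_waveforms_csv",
    "read_point_cloud",
]

_UNIT_FACTORS = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def _f12(x: float) -> float:
    """Float fixed to 12 significant digits (stable YAML round-trips)."""
    return float(f"{float(x):.12g}")


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------


def read_trc(path) -> MarkerTrajectorySet:
    """Load a TRC file; coordinates are converted to mm when the header
    declares another unit (with a warning)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError("TRC file has fewer than 6 lines", line=len(lines))
    head_keys = lines[1].split("\t")
    head_vals = lines[2].split("\t")
    header = dict(zip(head_keys, head_vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
        units = header.get("Units", "mm")
    except (KeyError, ValueError) as exc:
        raise ParseError(f"malformed TRC header: {exc}", line=3) from None
    if units not in _UNIT_FACTORS:
        raise ParseError(f"unknown units '{units}'", line=3)
    factor = _UNIT_FACTORS[units]
    if factor != 1.0:
        warnings.warn(f"TRC units '{units}' converted to mm")

    name_cells = lines[3].split("\t")
    markers = [c for c in name_cells[2:] if c.strip()]
    if len(markers) != n_markers:
        raise ParseError(
            f"header declares {n_markers} markers but row 4 names {len(markers)}", line=4
        )

    rows = [ln for ln in lines[5:] if ln.strip()]
    n = len(rows)
    pos = np.full((n, n_markers, 3), np.nan)
    vis = np.zeros((n, n_markers), dtype=bool)
    for k, ln in enumerate(rows):
        cells = ln.split("\t")
        expected = 2 + 3 * n_markers
        if len(cells) < expected:
            cells = cells + [""] * (expected - len(cells))
        for j in range(n_markers):
            triple = cells[2 + 3 * j : 5 + 3 * j]
            if all(c.strip() for c in triple):
                try:
                    pos[k, j] = [float(c) * factor for c in triple]
                except ValueError:
                    raise ParseError(f"non-numeric coordinate '{triple}'", line=6 + k) from None
                vis[k, j] = True
    return MarkerTrajectorySet(rate=rate, markers=tuple(markers), positions=pos, visible=vis)


def write_trc(path, traj: MarkerTrajectorySet) -> None:
    """Write a TRC file (mm, 6 decimals; invisible samples as blank cells)."""
    path = Path(path)
    n, m = traj.positions.shape[:2]
    out = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{traj.rate:g}\t{traj.rate:g}\t{n}\t{m}\tmm\t{traj.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(traj.markers) + "\t\t",
        "\t\t" + "\t".join(f"X{j+1}\tY{j+1}\tZ{j+1}" for j in range(m)),
    ]
    for k in range(n):
        cells = [str(k + 1), f"{k / traj.rate:.6f}"]
        for j in range(m):
            if traj.visible[k, j]:
                cells.extend(f"{c:.6f}" for c in traj.positions[k, j])
            else:
                cells.extend(["", "", ""])
        out.append("\t".join(cells))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# marker CSV
# ---------------------------------------------------------------------------


def read_markers_csv(path, rate: float | None = None) -> MarkerTrajectorySet:
    """Load marker trajectories from CSV (wide or long form; mm).

    Wide: ``frame, [time,] M_x, M_y, M_z`` per marker.  Long: ``frame,
    marker, x, y, z``.  A ``rate`` column (Hz, constant) or the ``rate``
    argument supplies the sampling rate; defaults to 100 Hz.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise InvalidArgumentError(f"{path}: no frames")
    cols = list(df.columns)
    if rate is None:
        rate = float(df["rate"].iloc[0]) if "rate" in cols else 100.0
    if {"marker", "x", "y", "z"}.issubset(cols):
        if "frame" not in cols:
            raise ParseError("long-format CSV is missing the 'frame' column")
        if df.duplicated(subset=["frame", "marker"]).any():
            raise ParseError("duplicate (frame, marker) rows")
        markers = tuple(sorted(df["marker"].unique()))
        frames = np.sort(df["frame"].unique())
        idx = {f: i for i, f in enumerate(frames)}
        jdx = {m: j for j, m in enumerate(markers)}
        pos = np.full((len(frames), len(markers), 3), np.nan)
        for _, row in df.iterrows():
            pos[idx[row["frame"]], jdx[row["marker"]]] = (row["x"], row["y"], row["z"])
        vis = np.all(np.isfinite(pos), axis=2)
        return MarkerTrajectorySet(rate=rate, markers=markers, positions=pos, visible=vis)

    if "frame" not in cols:
        raise ParseError("wide-format CSV is missing the 'frame' column")
    suffixes = ("_x", "_y", "_z")
    markers = []
    for c in cols:
        if c.endswith("_x"):
            stem = c[:-2]
            missing = [stem + s for s in suffixes if stem + s not in cols]
            if missing:
                raise ParseError(f"missing column '{missing[0]}'")
            markers.append(stem)
    if not markers:
        raise ParseError("no marker coordinate columns (expected NAME_x/_y/_z)")
    pos = np.stack(
        [df[[m + s for s in suffixes]].to_numpy(dtype=float) for m in markers], axis=1
    )
    vis = np.all(np.isfinite(pos), axis=2)
    return MarkerTrajectorySet(rate=rate, markers=tuple(markers), positions=pos, visible=vis)


# ---------------------------------------------------------------------------
# model YAML / regression JSON
# ---------------------------------------------------------------------------


def model_to_dict(model: MultibodyModel) -> dict:
    def mat(tf: RigidTransform):
        return [[_f12(v) for v in row] for row in tf.as_matrix().tolist()]

    def vec(v):
        return [_f12(x) for x in np.asarray(v).tolist()]

    return {
        "frames": {s: mat(model.frames[s]) for s in SEGMENTS},
        "templates": {
            s: {k: vec(v) for k, v in sorted(model.templates[s].items())} for s in SEGMENTS
        },
        "centres": {
            "hjc_in_pelvis": vec(model.centres.hjc_in_pelvis),
            "hjc_in_femur": vec(model.centres.hjc_in_femur),
            "sjc_in_femur": vec(model.centres.sjc_in_femur),
            "sjc_in_tibia": vec(model.centres.sjc_in_tibia),
        },
        "weights": {k: _f12(v) for k, v in sorted(model.weights.items())},
        "dynamic_markers": {s: list(model.dynamic_markers[s]) for s in SEGMENTS},
    }


def model_from_dict(d: dict) -> MultibodyModel:
    frames = {s: RigidTransform.from_matrix(np.array(d["frames"][s])) for s in SEGMENTS}
    templates = {
        s: {k: np.array(v, dtype=float) for k, v in d["templates"][s].items()}
        for s in SEGMENTS
    }
    centres = JointCentres(**{k: np.array(v, dtype=float) for k, v in d["centres"].items()})
    return assemble_model(
        frames,
        templates,
        centres,
        weights=d.get("weights"),
        dynamic_markers=d.get("dynamic_markers"),
    )


def save_model(path, model: MultibodyModel) -> None:
    """Serialize a model to YAML (or JSON if the suffix is .json)."""
    d = model_to_dict(model)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))


def load_model(path) -> MultibodyModel:
    path = Path(path)
    text = path.read_text()
    d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(d)


def save_regression(path, model: HjcRegressionModel) -> None:
    d = {
        "x_coeffs": [_f12(c) for c in model.x_coeffs],
        "z_coeffs": [_f12(c) for c in model.z_coeffs],
        "residual_rms": [_f12(c) for c in model.residual_rms],
        "n_training": model.n_training,
    }
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_regression(path) -> HjcRegressionModel:
    d = json.loads(Path(path).read_text())
    return HjcRegressionModel(
        x_coeffs=tuple(d["x_coeffs"]),
        z_coeffs=tuple(d["z_coeffs"]),
        residual_rms=tuple(d.get("residual_rms", (0.0, 0.0))),
        n_training=int(d.get("n_training", 0)),
    )


# ---------------------------------------------------------------------------
# poses CSV
# ---------------------------------------------------------------------------


def write_poses_csv(path, result: TrackingResult) -> None:
    """One row per frame: validity, convergence, residual, and each
    segment's 4x4 pose flattened row-major."""
    cols = {"frame": np.arange(result.n_frames)}
    cols["valid"] = result.frame_valid.astype(int)
    cols["converged"] = result.converged.astype(int)
    cols["residual_mm"] = result.residual_rms
    for seg in SEGMENTS:
        R = result.rotations[seg]
        t = result.translations[seg]
        for i in range(4):
            for j in range(4):
                name = f"{seg}_m{i}{j}"
                if i < 3 and j < 3:
                    cols[name] = R[:, i, j]
                elif i < 3:
                    cols[name] = t[:, i]
                else:
                    cols[name] = np.full(result.n_frames, 1.0 if j == 3 else 0.0)
    df = pd.DataFrame(cols)
    df.to_csv(path, index=False, float_format="%.9g")


def read_poses_csv(path, rate: float = 100.0) -> TrackingResult:
    df = pd.read_csv(path)
    n = len(df)
    rotations, translations = {}, {}
    for seg in SEGMENTS:
        R = np.empty((n, 3, 3))
        t = np.empty((n, 3))
        for i in range(3):
            t[:, i] = df[f"{seg}_m{i}3"]
            for j in range(3):
                R[:, i, j] = df[f"{seg}_m{i}{j}"]
        rotations[seg], translations[seg] = R, t
    valid = df["valid"].to_numpy(dtype=bool)
    return TrackingResult(
        method="loaded",
        rate=rate,
        rotations=rotations,
        translations=translations,
        residual_rms=df["residual_mm"].to_numpy(dtype=float),
        frame_valid=valid,
        converged=df["converged"].to_numpy(dtype=bool),
        iterations=np.zeros(n, dtype=int),
    )


# ---------------------------------------------------------------------------
# waveform CSV
# ---------------------------------------------------------------------------

_WAVE_COLUMNS = [
    f"{joint}_{comp}"
    for joint in ("hip", "stifle")
    for comp in ("flexion_extension", "adduction_abduction", "internal_external")
]


def write_waveforms_csv(path, cycles: list) -> None:
    """Per-cycle 101-point joint-angle waveforms.

    ``cycles`` is a list of dicts ``{'hip': (101, 3), 'stifle': (101, 3)}``.
    Layout: one row per (cycle, % gait cycle); angle columns in degrees
    with 6 decimals.
    """
    rows = []
    for c, cyc in enumerate(cycles):
        hip = np.asarray(cyc["hip"])
        stifle = np.asarray(cyc["stifle"])
        for p in range(hip.shape[0]):
            rows.append([c, p] + list(hip[p]) + list(stifle[p]))
    df = pd.DataFrame(rows, columns=["cycle", "percent"] + _WAVE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.6f")


def read_waveforms_csv(path) -> list:
    df = pd.read_csv(path)
    out = []
    for c in sorted(df["cycle"].unique()):
        sub = df[df["cycle"] == c].sort_values("percent")
        out.append(
            {
                "hip": sub[_WAVE_COLUMNS[:3]].to_numpy(dtype=float),
                "stifle": sub[_WAVE_COLUMNS[3:]].to_numpy(dtype=float),
            }
        )
    return out


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------


def read_point_cloud(path) -> np.ndarray:
    """Vertices from a CSV (x,y,z header) or ASCII PLY file, as (n, 3) mm."""
    path = Path(path)
    if path.suffix.lower() == ".ply":
        lines = path.read_text().splitlines()
        if not lines or lines[0].strip() != "ply":
            raise ParseError("not a PLY file", line=1)
        n_vertex = None
        end = None
        for i, ln in enumerate(lines):
            parts = ln.split()
            if parts[:2] == ["element", "vertex"]:
                n_vertex = int(parts[2])
            if ln.strip() == "end_header":
                end = i
                break
        if n_vertex is None or end is None:
            raise ParseError("PLY header missing vertex element or end_header")
        data = [
            [float(v) for v in ln.split()[:3]]
            for ln in lines[end + 1 : end + 1 + n_vertex]
        ]
        return np.array(data, dtype=float)
    df = pd.read_csv(path)
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise ParseError(f"point cloud CSV missing column '{c}'")
    return df[["x", "y", "z"]].to_numpy(dtype=float)
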