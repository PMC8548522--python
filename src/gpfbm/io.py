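"""Readers and writers: trajectory CSV, results JSON/CSV, TIFF stacks.

Trajectory CSV schema (one row per detection):

    track_id, frame, time_s, x, y[, z][, group_id][, sigma_x, sigma_y[, sigma_z]]

Occlusions are encoded as absent rows; rows with missing coordinates (NaN)
are accepted on input and converted to occlusions.  Coordinates are
continuous pixel units by default; an optional pixel-size scale converts to
μm at the I/O boundary only.  Readers reject rather than silently coerce
malformed inputs, naming the offending rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import Trajectory

logger = logging.getLogger("gpfbm")

REQUIRED_COLUMNS = ("track_id", "frame", "time_s", "x", "y")


class TrajectoryParseError(ValueError):
    """Malformed trajectory CSV (missing columns, duplicates, bad times)."""


@dataclass
class RunConfig:
    """Serializable run settings; round-trips losslessly through JSON."""

    min_track_length: int = 10
    mh_samples: int = 10_000
    mh_burn_in: int = 2_000
    max_lag_fraction: float = 0.1
    ddb_max_lag: int = 10
    seed: int = 0
    pixel_size: float = 1.0
    input_path: str = ""
    output_path: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def read_trajectories(path, pixel_size: float = 1.0) -> dict[str, list[Trajectory]]:
    """Read a trajectory CSV, validated, grouped by group_id.

    Rows with NaN coordinates become occlusions (dropped with a notice);
    duplicate (track, frame) pairs and non-monotone times are parse errors
    naming the offending row numbers.  Missing sigma columns default
    loc_errors to 0 with a logged notice.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"missing required columns: {missing}")
    if "group_id" not in df.columns:
        df["group_id"] = "0"
    dims = ["x", "y"] + (["z"] if "z" in df.columns else [])
    sigma_cols = [f"sigma_{d}" for d in dims]
    have_sigma = all(c in df.columns for c in sigma_cols)
    if not have_sigma:
        logger.info("no sigma_* columns in %s; localization errors default to 0", path)

    nan_mask = df[dims].isna().any(axis=1)
    if nan_mask.any():
        logger.info("dropping %d rows with missing coordinates (occlusions)",
                    int(nan_mask.sum()))
        df = df[~nan_mask]

    dup = df.duplicated(subset=["track_id", "frame"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()  # 1-based incl. header
        raise TrajectoryParseError(f"duplicate (track_id, frame) at file rows {rows}")

    out: dict[str, list[Trajectory]] = {}
    for (gid, tid), sub in df.groupby(["group_id", "track_id"], sort=True):
        sub = sub.sort_values("frame")
        times = sub["time_s"].to_numpy(dtype=float)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            bad = sub.index[np.where(np.diff(times) <= 0)[0] + 1] + 2
            raise TrajectoryParseError(
                f"non-increasing time_s for track {tid!r} at file rows {bad.tolist()}"
            )
        pos = sub[dims].to_numpy(dtype=float) * pixel_size
        if have_sigma:
            sig = sub[sigma_cols].to_numpy(dtype=float) * pixel_size
        else:
            sig = np.zeros_like(pos)
        out.setdefault(str(gid), []).append(
            Trajectory(times=times, positions=pos, loc_errors=sig,
                       track_id=str(tid), group_id=str(gid))
        )
    return out


def write_trajectories(trajs: list[Trajectory], path, pixel_size: float = 1.0) -> None:
    """Write trajectories to the canonical CSV schema (occlusions = absent rows)."""
    rows = []
    for tr in trajs:
        dims = "xyz"[: tr.n_dims]
        dt = float(np.min(np.diff(tr.times))) if tr.n_points > 1 else 1.0
        frames = np.rint((tr.times - tr.times[0]) / dt).astype(int)
        for i in range(tr.n_points):
            row = {"track_id": tr.track_id, "group_id": tr.group_id,
                   "frame": int(frames[i]), "time_s": float(tr.times[i])}
            for d, name in enumerate(dims):
                row[name] = float(tr.positions[i, d] / pixel_size)
                row[f"sigma_{name}"] = float(tr.loc_errors[i, d] / pixel_size)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(results: dict, path) -> Path:
    """Write a results dictionary to JSON plus a flat per-track CSV table.

    ``results`` holds per-track records under "tracks" (each a dict of
    parameters/intervals) and optional per-group substrate blocks under
    "groups".  Floats survive the round trip to 1e−12; integers exactly.
    Returns the JSON path; the CSV sits next to it with suffix ``.csv``.
    """
    path = Path(path)
    payload = {"software": {"name": "gpfbm", "version": __version__}}
    payload.update(_jsonable(results))
    path.write_text(json.dumps(payload, indent=1))
    tracks = results.get("tracks", [])
    flat = []
    for rec in tracks:
        row = {}
        for k, v in rec.items():
            if isinstance(v, (int, float, str, np.floating, np.integer)):
                row[k] = _jsonable(v)
            elif isinstance(v, (list, tuple, np.ndarray)):
                arr = np.asarray(v).ravel()
                for i, item in enumerate(arr):
                    row[f"{k}_{i}"] = _jsonable(item)
        flat.append(row)
    pd.DataFrame(flat).to_csv(path.with_suffix(".csv"), index=False)
    return path


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())


def read_tiff_stack(path) -> np.ndarray:
    """Read a (possibly multi-page) TIFF into a (T, H, W) float array."""
    import tifffile

    arr = tifffile.imread(path)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def fit_result_record(track_id, group_id, fit, chain=None) -> dict:
    """Flatten a FitResult (+ optional PosteriorChain) into a results row."""
    rec = {
        "track_id": str(track_id),
        "group_id": str(group_id),
        "D_alpha": fit.params.D_alpha,
        "alpha": fit.params.alpha,
        "mu": fit.params.mu,
        "log_posterior": fit.log_posterior,
        "converged": bool(fit.converged),
    }
    if chain is not None:
        for name in ("D_alpha", "alpha"):
            lo, hi = chain.credible_interval(name)
            rec[f"{name}_ci95"] = [lo, hi]
        rec["mh_acceptance"] = chain.acceptance_rate
        rec["mh_seed"] = chain.seed
    return rec
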