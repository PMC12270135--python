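"""Readers, writers and configuration for the analysis pipeline.

Trajectory tables are CSV with columns ``traj_id, frame, x, y`` (positions
in µm, or in pixels with an ingest-time conversion, default 0.7 µm/px).
Frame indices are 0-based and time is ``frame / frame_rate``; the gradient
axis is ``+y`` throughout the package.  Gaps in the frame index split a
trajectory into separately identified segments.

Summaries are versioned JSON; NaN statistics are serialized as explicit
nulls, never dropped.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import yaml

from .response import (
    BetaBasal,
    EmpiricalBasal,
    HeterogeneousResponse,
    HomogeneousResponse,
    ResponseModel,
)
from .simulator import GradientChannel, SimConfig
from .trackstats import Trajectory

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "write_summary",
    "read_summary",
    "model_from_dict",
    "model_to_dict",
    "channel_from_dict",
    "sim_config_from_dict",
    "load_yaml_config",
    "config_hash",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1

_REQUIRED = ("traj_id", "frame", "x", "y")


def read_trajectories(path, unit: str = "um", pixel_size: float = 0.7,
                      frame_rate: float = 50.0,
                      ) -> Tuple[List[Trajectory], List[str]]:
    """Read a trajectory CSV into :class:`~runtumble.trackstats.Trajectory`
    objects.

    ``unit="px"`` converts coordinates with ``pixel_size`` µm/px.  Frames
    are sorted per trajectory; a gap in the frame index splits the
    trajectory into separate segments with derived ids.  Returns the
    trajectories and a log of splits/drops.
    """
    if unit not in ("um", "px"):
        raise ValueError("unit must be 'um' or 'px'")
    df = pd.read_csv(path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want in _REQUIRED:
        if want in cols:
            rename[cols[want]] = want
        elif want in ("x", "y") and f"{want}_um" in cols:
            rename[cols[f"{want}_um"]] = want
        else:
            raise ValueError(f"trajectory table is missing column '{want}'")
    df = df.rename(columns=rename)
    for col in ("frame", "x", "y"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    if df.duplicated(subset=["traj_id", "frame"]).any():
        raise ValueError("duplicate (traj_id, frame) entries")

    scale = pixel_size if unit == "px" else 1.0
    out: List[Trajectory] = []
    log: List[str] = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(dtype=np.int64)
        x = grp["x"].to_numpy(dtype=float) * scale
        y = grp["y"].to_numpy(dtype=float) * scale
        breaks = np.flatnonzero(np.diff(frames) != 1) + 1
        pieces = np.split(np.arange(frames.size), breaks)
        if len(pieces) > 1:
            log.append(f"trajectory {tid}: split into {len(pieces)} segments "
                       "at frame gaps")
        for j, idx in enumerate(pieces):
            seg_id = tid if len(pieces) == 1 else f"{tid}_{j}"
            if idx.size < 2:
                log.append(f"trajectory {seg_id}: dropped (fewer than 2 frames)")
                continue
            out.append(Trajectory(
                traj_id=seg_id, x=x[idx], y=y[idx], frame_rate=frame_rate,
                t0=float(frames[idx[0]]) / frame_rate))
    return out, log


def write_trajectories(tracks: Sequence[Trajectory], path) -> None:
    """Write tracks in the ingest schema (coordinates in µm)."""
    frames = []
    for traj in tracks:
        n = traj.n_frames
        frames.append(pd.DataFrame({
            "traj_id": traj.traj_id,
            "frame": np.arange(n),
            "t_s": traj.t0 + np.arange(n) / traj.frame_rate,
            "x": traj.x,
            "y": traj.y,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# JSON summaries


def _sanitize(obj):
    """Make an object JSON-serializable, mapping non-finite floats to null."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (float, np.floating)):
        f = float(obj)
        return f if math.isfinite(f) else None
    if is_dataclass(obj) and not isinstance(obj, type):
        return _sanitize(asdict(obj))
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_summary(results: Dict, path, provenance: Optional[Dict] = None) -> None:
    """Write a versioned JSON summary with explicit nulls for NaN values."""
    payload = {"schema_version": SCHEMA_VERSION}
    if provenance is not None:
        payload["provenance"] = _sanitize(provenance)
    payload.update(_sanitize(results))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     allow_nan=False) + "\n")


def read_summary(path) -> Dict:
    return json.loads(Path(path).read_text())


def config_hash(config: Dict) -> str:
    """Stable hash of a configuration mapping, for provenance records."""
    canon = json.dumps(_sanitize(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# structured-text configuration


def model_from_dict(d: Dict) -> ResponseModel:
    """Build a response model from a configuration mapping.

    ``kind: homogeneous`` takes tb0, tb_inf, k_r, h_r; ``kind:
    heterogeneous`` takes mu_log_k, sigma_log_k, rho, hill_cell and a
    ``basal`` block (``{a, b}`` for a Beta distribution or ``{values:
    [...]}`` for an empirical sample); ``kind: r1_homogeneous`` /
    ``r1_heterogeneous`` load the built-in reference models.
    """
    d = dict(d)
    kind = d.pop("kind")
    if kind == "homogeneous":
        return HomogeneousResponse(**d)
    if kind == "heterogeneous":
        basal = d.pop("basal")
        if "values" in basal:
            dist = EmpiricalBasal(np.asarray(basal["values"], dtype=float))
        else:
            dist = BetaBasal(float(basal["a"]), float(basal["b"]))
        return HeterogeneousResponse(basal=dist, **d)
    if kind in ("r1_homogeneous", "r1_heterogeneous"):
        from . import reference
        fn = (reference.r1_homogeneous if kind == "r1_homogeneous"
              else reference.r1_heterogeneous)
        return fn(**d)
    raise ValueError(f"unknown model kind {kind!r}")


def model_to_dict(model: ResponseModel) -> Dict:
    if isinstance(model, HomogeneousResponse):
        return {"kind": "homogeneous", "tb0": model.tb0, "tb_inf": model.tb_inf,
                "k_r": model.k_r, "h_r": model.h_r}
    basal = model.basal
    if isinstance(basal, BetaBasal):
        bd = {"a": basal.a, "b": basal.b}
    else:
        bd = {"values": list(map(float, basal.values))}
    return {"kind": "heterogeneous", "mu_log_k": model.mu_log_k,
            "sigma_log_k": model.sigma_log_k, "rho": model.rho,
            "hill_cell": model.hill_cell, "basal": bd}


def channel_from_dict(d: Dict) -> GradientChannel:
    return GradientChannel(**d)


def sim_config_from_dict(d: Dict) -> SimConfig:
    d = dict(d)
    if isinstance(d.get("tau_adapt"), str):
        d["tau_adapt"] = float(d["tau_adapt"])
    return SimConfig(**d)


def load_yaml_config(path) -> Dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config file not found: {p}")
    with open(p) as fh:
        return yaml.safe_load(fh)
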