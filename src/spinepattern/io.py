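"""Configuration files, state checkpoints and raster export."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .params import Grid, ModelParams, SimSchedule, preset
from .rd_core import FieldState, Trajectory


def load_config(path: str | Path) -> dict:
    """Read a YAML/JSON run configuration.

    Recognised blocks: ``params`` (either ``{"preset": name}`` plus
    overrides, or explicit coefficients), ``grid``, ``schedule`` and
    ``protocol`` (free-form, passed through).  Returns a dict with
    instantiated ``ModelParams``/``Grid``/``SimSchedule`` objects.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out: dict = {"protocol": raw.get("protocol", {})}
    pblock = dict(raw.get("params", {}))
    name = pblock.pop("preset", None)
    out["params"] = preset(name, **pblock) if name else ModelParams(**pblock)
    out["grid"] = Grid(**raw.get("grid", {}))
    out["schedule"] = SimSchedule(**raw.get("schedule", {}))
    return out


def dump_config(
    params: ModelParams,
    grid: Grid,
    schedule: SimSchedule,
    path: str | Path,
    protocol: dict | None = None,
) -> None:
    """Write a configuration that :func:`load_config` round-trips."""
    doc = {
        "params": asdict(params),
        "grid": asdict(grid),
        "schedule": asdict(schedule),
        "protocol": protocol or {},
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def save_checkpoint(state: FieldState, path: str | Path,
                    provenance: dict | None = None) -> None:
    """Single-file checkpoint of the four fields, t and optional provenance."""
    np.savez_compressed(
        Path(path),
        A=state.A, H=state.H, S=state.S, Y=state.Y,
        t=np.float64(state.t),
        provenance=json.dumps(provenance or {}),
    )


def load_checkpoint(path: str | Path) -> tuple[FieldState, dict]:
    """Read a checkpoint written by :func:`save_checkpoint`."""
    with np.load(Path(path), allow_pickle=False) as d:
        state = FieldState(d["A"], d["H"], d["S"], d["Y"], float(d["t"]))
        prov = json.loads(str(d["provenance"]))
    return state, prov


def export_raster(array: np.ndarray, path: str | Path,
                  binary: bool = False) -> None:
    """Write a field or mask as an 8-bit PNG/TIFF (scaled to full range)."""
    import imageio.v3 as iio

    a = np.asarray(array, dtype=float)
    if binary:
        img = (a > 0).astype(np.uint8) * 255
    else:
        lo, hi = float(a.min()), float(a.max())
        span = hi - lo if hi > lo else 1.0
        img = np.round((a - lo) / span * 255).astype(np.uint8)
    iio.imwrite(Path(path), img)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary silhouette from an image file (nonzero = true)."""
    import imageio.v3 as iio

    img = iio.imread(Path(path))
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return np.asarray(img) > 0


def export_trajectory(traj: Trajectory, out_dir: str | Path,
                      field: str = "Y", binary: bool = False) -> list[Path]:
    """Write a trajectory as a numbered image sequence; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, snap in enumerate(traj.snapshots):
        p = out_dir / f"{field}_{i:04d}.png"
        export_raster(getattr(snap, field), p, binary=binary)
        paths.append(p)
    return paths
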