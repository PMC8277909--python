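"""Trajectory containers on disk: HDF5 movies plus JSON manifests."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .model import Trajectory
from .waves import ActivityMovie

__all__ = ["save_trajectory", "load_movies", "load_manifest"]


def save_trajectory(traj: Trajectory, out_dir, stem: str = "run") -> Path:
    """Write one dataset per layer plus a JSON manifest alongside.

    Each dataset is (T, rows, cols) with attributes ``dt``,
    ``record_every``, ``seed`` and ``preset``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h5_path = out_dir / f"{stem}.h5"
    cfg = traj.config
    with h5py.File(h5_path, "w") as f:
        for layer, movie in traj.movies.items():
            d = f.create_dataset(layer, data=movie, compression="gzip")
            d.attrs["dt"] = cfg.dt
            d.attrs["record_every"] = cfg.record_every
            d.attrs["seed"] = cfg.seed
            d.attrs["preset"] = cfg.preset
    (out_dir / f"{stem}.manifest.json").write_text(
        json.dumps(traj.manifest, indent=1, default=_jsonable)
    )
    return h5_path


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    return str(x)


def load_movies(h5_path, frame_dt: float | None = None,
                pixel_pitch: float | None = None) -> dict[str, ActivityMovie]:
    """Read every layer dataset of a trajectory file as ActivityMovies."""
    out: dict[str, ActivityMovie] = {}
    with h5py.File(h5_path, "r") as f:
        for name in f:
            d = f[name]
            dt = frame_dt if frame_dt is not None \
                else float(d.attrs.get("record_every", 2.0))
            kw = {}
            if pixel_pitch is not None:
                kw["pixel_pitch"] = pixel_pitch
            out[name] = ActivityMovie(np.array(d), frame_dt=dt, **kw)
    return out


def load_manifest(h5_path) -> dict | None:
    p = Path(h5_path)
    mp = p.with_name(p.stem + ".manifest.json")
    if mp.exists():
        return json.loads(mp.read_text())
    return None
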