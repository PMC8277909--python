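"""Synthetic activity movies with known ground truth.

These geometric fixtures (planar bands, expanding rings, rotating spiral
arms, staircase "lurching" fronts) exercise the wave-analysis estimators
independently of the network simulator: every generated movie carries a
ground-truth record (speed, direction, period, stall fraction) that the
estimators must recover.  They make no attempt at dynamical realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .model import SimulationConfig, Simulation
from .waves import ActivityMovie, DEFAULT_FRAME_DT_MS, DEFAULT_PIXEL_PITCH_MM

__all__ = ["FixtureSpec", "GroundTruth", "make_movie", "make_micro_network"]

KINDS = ("planar", "radial", "rotating", "staircase", "constant")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic movie."""

    kind: str = "planar"
    speed: float = 1.0        # px / frame (angular speed for 'rotating',
    #                           rad/frame)
    direction: float = 0.0    # degrees; 0 = +columns, 90 = -rows (up)
    period: int = 0           # staircase: frames per advance cycle
    band_width: float = 3.0   # px
    noise_sd: float = 0.0
    rows: int = 60
    cols: int = 60
    n_frames: int = 50
    amplitude: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if min(self.rows, self.cols, self.n_frames) <= 0:
            raise ValueError("shape must be positive")


@dataclass
class GroundTruth:
    """What the analysis toolkit should recover from the fixture."""

    kind: str
    speed_px_per_frame: float | None
    speed_cm_s: float | None
    direction_deg: float | None
    period_frames: float | None
    stall_fraction: float | None

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def _axis_coord(spec: FixtureSpec) -> np.ndarray:
    """Signed coordinate of every pixel along the travel direction."""
    th = np.radians(spec.direction)
    rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols),
                         indexing="ij")
    # direction convention: 0 deg -> +cols, 90 deg -> -rows (up)
    return cc * np.cos(th) - rr * np.sin(th)


def make_movie(spec: FixtureSpec,
               frame_dt: float = DEFAULT_FRAME_DT_MS,
               pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM):
    """Render a fixture; returns ``(ActivityMovie, GroundTruth)``.

    Deterministic under ``spec.seed``.  The px/frame to cm/s conversion
    uses the supplied calibration (defaults: 0.4 mm pitch, 2 ms frames,
    i.e. 20 cm/s per px/frame).
    """
    rng = np.random.default_rng(spec.seed)
    frames = np.zeros((spec.n_frames, spec.rows, spec.cols))
    k = spec.amplitude
    cm_per_px_frame = pixel_pitch / frame_dt * 100.0

    if spec.kind == "constant":
        truth = GroundTruth("constant", 0.0, 0.0, None, None, None)
    elif spec.kind in ("planar", "staircase"):
        coord = _axis_coord(spec)
        lo = coord.min() - spec.band_width
        span = coord.max() - lo + spec.band_width
        if spec.kind == "planar":
            pos = lo + spec.speed * np.arange(spec.n_frames)
            stall = 0.0
        else:
            period = max(int(spec.period), 1)
            cycles, phase = np.divmod(np.arange(spec.n_frames), period)
            jump = spec.speed * period  # advance once per cycle
            pos = lo + cycles * jump + np.where(phase == 0, 0.0, 0.0)
            stall = (period - 1) / period
        pos = np.mod(pos - lo, span) + lo
        for t in range(spec.n_frames):
            band = (coord >= pos[t]) & (coord < pos[t] + spec.band_width)
            frames[t][band] = k
        truth = GroundTruth(
            spec.kind,
            spec.speed,
            spec.speed * cm_per_px_frame,
            spec.direction % 360.0,
            span / spec.speed if spec.speed > 0 else None,
            stall,
        )
    elif spec.kind == "radial":
        rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols),
                             indexing="ij")
        r = np.hypot(rr - spec.rows / 2, cc - spec.cols / 2)
        for t in range(spec.n_frames):
            radius = spec.speed * t
            ring = (r >= radius) & (r < radius + spec.band_width)
            frames[t][ring] = k
        truth = GroundTruth("radial", spec.speed,
                            spec.speed * cm_per_px_frame, None, None, 0.0)
    elif spec.kind == "rotating":
        # Archimedean spiral arm rotating at a fixed angular rate
        rr, cc = np.meshgrid(np.arange(spec.rows), np.arange(spec.cols),
                             indexing="ij")
        y = -(rr - spec.rows / 2)
        x = cc - spec.cols / 2
        r = np.hypot(x, y)
        phi = np.arctan2(y, x)
        pitch = 2 * np.pi / max(spec.rows, spec.cols) * 4
        width = spec.band_width * pitch
        omega = spec.speed  # rad / frame
        for t in range(spec.n_frames):
            phase = np.mod(phi - r * pitch - omega * t, 2 * np.pi)
            arm = (phase < width) & (r > 1.5)
            frames[t][arm] = k
        truth = GroundTruth(
            "rotating", None, None, None,
            2 * np.pi / omega if omega > 0 else None, None)
    else:  # pragma: no cover - guarded by FixtureSpec
        raise AssertionError

    if spec.noise_sd > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
    return ActivityMovie(frames, frame_dt, pixel_pitch), truth


def make_micro_network(rows: int = 3, cols: int = 3,
                       kind: str = "three_layer",
                       seed: int = 0, **config_kw) -> Simulation:
    """Tiny fully auditable model instance for hand-checkable inputs.

    Boundary absorption is disabled and fractions default to 1 so every
    projection is active and input-field row sums can be verified by
    hand against the coupling equations.
    """
    defaults = dict(
        kind=kind, rows=rows, cols=cols, duration=1.0, seed=seed,
        boundary_width=0, intra_fraction=1.0, e_fraction=1.0,
        m_fraction=1.0, w_fraction=1.0, th_fraction=1.0, sigma=0.0,
        triggers=(),
    )
    defaults.update(config_kw)
    return Simulation(SimulationConfig(**defaults))
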