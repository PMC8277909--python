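"""Quantification of activity movies: wavefronts, speed, frequency, lurch.

The estimators mirror standard practice for multielectrode-array movies:
wavefronts are suprathreshold connected components (4-connectivity), the
wave speed is the mean nearest-edge displacement of wavefront boundary
pixels between consecutive frames, oscillation frequency is the spectral
peak of the spatial-mean trace, and the "lurch index" quantifies how
staggered the advance of a propagating front is along a kymograph line
(0 for a smooth constant-velocity front, the stall fraction for a
staircase-like front).

Spatial calibration defaults to a 60-pixel sheet spanning 24 mm (0.4 mm
pitch) recorded at one frame per 2 ms, under which one pixel per frame
equals 20 cm/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, signal, stats
from skimage import measure

__all__ = [
    "ActivityMovie",
    "WaveMetrics",
    "DEFAULT_PIXEL_PITCH_MM",
    "DEFAULT_FRAME_DT_MS",
    "segmentation_level",
    "segment_wavefront",
    "patch_count",
    "mask_boundary",
    "wave_speed",
    "mean_wave_speed",
    "MAX_PROPAGATION_CM_S",
    "kymograph",
    "dominant_frequency",
    "lurch_index",
    "wave_area_series",
    "wave_duration",
    "wave_direction",
    "compare_conditions",
    "movie_metrics",
]

DEFAULT_PIXEL_PITCH_MM = 0.4     # 24 mm sheet / 60 pixels
DEFAULT_FRAME_DT_MS = 2.0


@dataclass
class ActivityMovie:
    """Voltage frames of one layer plus spatial/temporal calibration."""

    frames: np.ndarray                       # (T, rows, cols)
    frame_dt: float = DEFAULT_FRAME_DT_MS    # ms
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM  # mm

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (T, rows, cols)")
        if self.pixel_pitch <= 0 or self.frame_dt <= 0:
            raise ValueError("calibration must be positive")


@dataclass
class WaveMetrics:
    """Summary metrics of one movie."""

    area_per_frame: np.ndarray
    patches_per_frame: np.ndarray
    mean_speed_cm_s: float | None
    dominant_frequency_hz: float | None
    duration_ms: float
    direction_deg: float | None
    lurch: float | None


def segmentation_level(frames: np.ndarray) -> float:
    """Midpoint between resting and spike-peak voltage, per movie.

    The resting level is the median; the spike peak is a high quantile
    (99.5th percentile of suprarest samples) rather than the raw maximum,
    which is dominated by a handful of drive-boosted cells.
    """
    frames = np.asarray(frames)
    rest = float(np.median(frames))
    hi = frames[frames > rest + 0.05]
    peak = float(np.percentile(hi, 99.5)) if hi.size else float(frames.max())
    return rest + 0.5 * (peak - rest)


def segment_wavefront(frame: np.ndarray, level: float):
    """Suprathreshold mask and its 4-connected component labels."""
    mask = np.asarray(frame) > level
    labels = measure.label(mask, connectivity=1)
    return mask, labels


def patch_count(frame: np.ndarray, level: float) -> int:
    """Number of 4-connected suprathreshold patches."""
    _, labels = segment_wavefront(frame, level)
    return int(labels.max())


def mask_boundary(mask: np.ndarray) -> np.ndarray:
    """Pixels of the mask with at least one non-mask 4-neighbour.

    Pixels on the array edge do not count as wavefront boundary unless
    they border a non-mask pixel inside the array (there is no front
    beyond the recorded sheet).
    """
    if not mask.any():
        return mask
    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1),
        border_value=1,
    )
    return mask & ~interior


def wave_speed(mask_prev: np.ndarray, mask_next: np.ndarray,
               frame_dt: float = DEFAULT_FRAME_DT_MS,
               pixel_pitch: float = DEFAULT_PIXEL_PITCH_MM) -> float | None:
    """Nearest-edge wave speed between two frames, in cm/s.

    For each boundary pixel of the later mask, the Euclidean distance to
    the closest boundary pixel of the earlier mask is computed; the mean
    distance, scaled by pixel pitch over frame interval, is the speed.
    Returns None (missing, not zero) if either mask is empty.
    """
    b_prev = mask_boundary(np.asarray(mask_prev, dtype=bool))
    b_next = mask_boundary(np.asarray(mask_next, dtype=bool))
    if not b_prev.any() or not b_next.any():
        return None
    dist = ndimage.distance_transform_edt(~b_prev)
    mean_px = float(dist[b_next].mean())
    mm_per_ms = mean_px * pixel_pitch / frame_dt
    return mm_per_ms * 100.0  # mm/ms == m/s -> cm/s


#: Physical ceiling on mesoscopic propagation used to separate wave
#: advance from de-novo nucleation in movie-level speed averages (cm/s).
MAX_PROPAGATION_CM_S = 300.0


def mean_wave_speed(movie: ActivityMovie, level: float | None = None,
                    max_speed_cm_s: float | None = MAX_PROPAGATION_CM_S,
                    ) -> float | None:
    """Mean nearest-edge speed over all consecutive propagating frames.

    Per-pixel displacements implying speeds above ``max_speed_cm_s`` are
    treated as nucleation events (a new wave appearing elsewhere on the
    sheet) rather than propagation of an existing front, and excluded
    from the average; pass ``None`` to keep every displacement.  The
    default ceiling is the top of the plausible mesoscopic propagation
    range at this calibration.
    """
    frames = movie.frames
    if frames.shape[0] < 2:
        raise ValueError("need at least two frames for a speed")
    if level is None:
        level = segmentation_level(frames)
    masks = frames > level
    cap_px = None
    if max_speed_cm_s is not None:
        cap_px = max_speed_cm_s / 100.0 * movie.frame_dt / movie.pixel_pitch
    speeds = []
    for k in range(len(masks) - 1):
        b_prev = mask_boundary(masks[k])
        b_next = mask_boundary(masks[k + 1])
        if not b_prev.any() or not b_next.any():
            continue
        d = ndimage.distance_transform_edt(~b_prev)[b_next]
        if cap_px is not None:
            d = d[d <= cap_px]
        if d.size:
            mm_per_ms = float(d.mean()) * movie.pixel_pitch / movie.frame_dt
            speeds.append(mm_per_ms * 100.0)
    return float(np.mean(speeds)) if speeds else None


def kymograph(movie: ActivityMovie, line, axis: str = "row") -> np.ndarray:
    """Space-time array of the movie along a scan line.

    ``line`` is a row index (``axis='row'``), a column index
    (``axis='col'``), or an explicit list of (row, col) points.
    """
    frames = movie.frames
    if isinstance(line, (int, np.integer)):
        if axis == "row":
            return frames[:, int(line), :]
        if axis == "col":
            return frames[:, :, int(line)]
        raise ValueError("axis must be 'row' or 'col'")
    pts = np.asarray(line)
    return frames[:, pts[:, 0], pts[:, 1]]


def dominant_frequency(trace: np.ndarray, frame_dt: float,
                       min_cycles: float = 4.0):
    """Spectral-peak frequency (Hz) of a trace sampled every frame_dt ms.

    The zero bin is excluded.  Returns ``(freq, confident)``; a constant
    trace yields ``(None, False)`` and a trace shorter than
    ``min_cycles`` of the found peak is flagged low-confidence.
    """
    trace = np.asarray(trace, dtype=float)
    x = trace - trace.mean()
    if len(x) < 4 or np.allclose(x, 0):
        return None, False
    fs = 1000.0 / frame_dt  # Hz
    freqs, power = signal.periodogram(x, fs=fs)
    k = int(np.argmax(power[1:])) + 1
    f = float(freqs[k])
    if f <= 0:
        return None, False
    span_cycles = len(x) / fs * f
    return f, bool(span_cycles >= min_cycles)


def _leading_positions(kymo: np.ndarray, level: float):
    """Per-frame suprathreshold extent along the scan line."""
    above = kymo > level
    pos_max = np.full(len(kymo), np.nan)
    pos_min = np.full(len(kymo), np.nan)
    for t in range(len(kymo)):
        idx = np.flatnonzero(above[t])
        if idx.size:
            pos_max[t] = idx[-1]
            pos_min[t] = idx[0]
    return pos_min, pos_max


def lurch_index(kymo: np.ndarray, frame_dt: float | None = None,
                level: float | None = None) -> float | None:
    """Stall fraction of the advancing front along a kymograph.

    Tracks the leading-edge envelope of the suprathreshold region from
    the first detection until the front reaches the end of the scan line
    (or detection ends).  The index is the fraction of inter-frame
    intervals during which the envelope does not advance: ~0 for a
    smooth constant-velocity front, the stall fraction for a staircase
    front, None if no propagating front is detectable.
    """
    kymo = np.asarray(kymo, dtype=float)
    if level is None:
        level = segmentation_level(kymo)
    pos_min, pos_max = _leading_positions(kymo, level)
    det = np.flatnonzero(np.isfinite(pos_max))
    if det.size < 2:
        return None
    first, last = det[0], det[-1]
    # propagation sign from net displacement of the leading edge
    if pos_max[last] - pos_max[first] >= pos_min[first] - pos_min[last]:
        sign, pos, end = 1.0, pos_max, kymo.shape[1] - 1
    else:
        sign, pos, end = -1.0, pos_min, 0
    adv = sign * pos
    env = adv[first]
    end_adv = sign * end
    stalls = 0
    total = 0
    for t in range(first + 1, last + 1):
        total += 1
        if np.isfinite(adv[t]) and adv[t] > env:
            env = adv[t]
        else:
            stalls += 1
        if env >= end_adv - 1:   # reached the far end of the line
            break
    if total == 0:
        return None
    return stalls / total


def wave_area_series(movie: ActivityMovie,
                     level: float | None = None) -> np.ndarray:
    """Number of suprathreshold cells per frame."""
    frames = movie.frames
    if level is None:
        level = segmentation_level(frames)
    return (frames > level).sum(axis=(1, 2))


def wave_duration(movie: ActivityMovie, level: float | None = None,
                  min_cells: int = 5) -> float:
    """Time from the first to the last frame with area above a cutoff."""
    area = wave_area_series(movie, level)
    alive = np.flatnonzero(area >= min_cells)
    if alive.size == 0:
        return 0.0
    return float((alive[-1] - alive[0]) * movie.frame_dt)


def wave_direction(masks: Sequence[np.ndarray]) -> float | None:
    """Mean centroid-displacement angle in degrees.

    Convention: 0 deg points along increasing columns (right), 90 deg
    along decreasing rows (up).  Returns None for a stationary or
    undetectable wave.
    """
    cents = []
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.any():
            cents.append(ndimage.center_of_mass(m))
        else:
            cents.append(None)
    steps = []
    for a, b in zip(cents[:-1], cents[1:]):
        if a is not None and b is not None:
            steps.append((b[0] - a[0], b[1] - a[1]))
    if not steps:
        return None
    drow = float(np.mean([s[0] for s in steps]))
    dcol = float(np.mean([s[1] for s in steps]))
    if drow == 0 and dcol == 0:
        return None
    return float(np.degrees(np.arctan2(-drow, dcol)) % 360.0)


def compare_conditions(a, b):
    """Two-sample comparison of a metric between conditions.

    Returns ``(mean_difference, sem_of_difference, t, p, degenerate)``.
    With identical samples the t statistic is 0 and p is 1 (flagged
    degenerate when both variances vanish).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two samples per condition")
    diff = float(a.mean() - b.mean())
    sem = float(np.sqrt(stats.sem(a) ** 2 + stats.sem(b) ** 2))
    degenerate = bool(np.var(a) == 0 and np.var(b) == 0)
    if degenerate:
        t, p = (0.0, 1.0) if diff == 0 else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b)
        t, p = float(t), float(p)
    return diff, sem, t, p, degenerate


def movie_metrics(movie: ActivityMovie, level: float | None = None,
                  scan_line: int | None = None) -> WaveMetrics:
    """All standard metrics of one movie in one pass."""
    frames = movie.frames
    if level is None:
        level = segmentation_level(frames)
    masks = frames > level
    area = masks.sum(axis=(1, 2))
    patches = np.array([
        int(measure.label(m, connectivity=1).max()) for m in masks
    ])
    speed = mean_wave_speed(movie, level)
    freq, _ = dominant_frequency(frames.mean(axis=(1, 2)), movie.frame_dt)
    duration = wave_duration(movie, level)
    direction = wave_direction(masks)
    if scan_line is None:
        scan_line = frames.shape[1] // 2
    lurch = lurch_index(kymograph(movie, scan_line), movie.frame_dt, level)
    return WaveMetrics(area, patches, speed, freq, duration, direction,
                       lurch)
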