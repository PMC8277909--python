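"""Multi-seed comparison protocols for the study's headline contrasts.

Each experiment reruns one comparison over a battery of seeds (default
5) and returns a tidy table with per-condition means, SEMs and
two-sample t-tests from :func:`thalwave.waves.compare_conditions`:

* ``speed_ordering`` -- cortical vs thalamic wave speed in the
  closed-loop default state.
* ``threshold_effects`` -- system threshold (cortical gating offset d4)
  vs wave speed and oscillation frequency.
* ``connectivity_area`` -- traveling-wave area vs intracortical
  connectivity in the isolated cortex.
* ``delay_duration`` -- wave-activity duration vs thalamocortical delay
  in the reduced model.
* ``ei_frequency`` -- cortical frequency under RE-inhibition x300 and
  thalamic frequency under CX->TC excitation x10.
* ``cortical_excitation`` -- cortical frequency and speed under doubled
  excitatory intracortical weights.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from . import waves as wv
from .model import run
from .presets import make_config

__all__ = ["EXPERIMENTS", "run_experiment"]


def _metrics(cfg, layer="cx"):
    traj = run(cfg)
    movie = wv.ActivityMovie(traj.movies[layer], frame_dt=cfg.record_every)
    interior = traj.movies[layer][:, 1:-1, 1:-1]
    freq, _ = wv.dominant_frequency(interior.mean(axis=(1, 2)),
                                    cfg.record_every)
    return dict(
        speed=wv.mean_wave_speed(movie),
        freq=freq,
        area=float(wv.wave_area_series(movie).mean()),
        duration=wv.wave_duration(movie),
    )


def _battery(preset: str, n_seeds: int, layer="cx", **kw):
    rows = []
    for seed in range(1, n_seeds + 1):
        cfg = make_config(preset, seed=seed, **kw)
        rows.append(_metrics(cfg, layer))
    return rows


def _summary_row(condition: str, metric: str, values):
    values = [v for v in values if v is not None]
    return dict(condition=condition, metric=metric,
                mean=float(np.mean(values)),
                sem=float(np.std(values, ddof=1) / np.sqrt(len(values)))
                if len(values) > 1 else 0.0,
                n=len(values))


def speed_ordering(n_seeds: int = 5, rows: int | None = None) -> pd.DataFrame:
    size = {} if rows is None else dict(rows=rows, cols=rows)
    out = []
    cx_speeds, tc_speeds = [], []
    for seed in range(1, n_seeds + 1):
        cfg = make_config("closed_loop_default", seed=seed, **size)
        traj = run(cfg)
        for layer, acc in (("cx", cx_speeds), ("tc", tc_speeds)):
            movie = wv.ActivityMovie(traj.movies[layer],
                                     frame_dt=cfg.record_every)
            acc.append(wv.mean_wave_speed(movie))
    out.append(_summary_row("cortex", "speed_cm_s", cx_speeds))
    out.append(_summary_row("thalamus", "speed_cm_s", tc_speeds))
    diff, sem, t, p, _ = wv.compare_conditions(cx_speeds, tc_speeds)
    out.append(dict(condition="cortex-vs-thalamus", metric="speed_cm_s",
                    mean=diff, sem=sem, n=n_seeds, t=t, p=p))
    return pd.DataFrame(out)


def threshold_effects(n_seeds: int = 5, rows: int | None = None) -> pd.DataFrame:
    """Lowered cortical threshold (smaller d4) vs speed and frequency."""
    size = {} if rows is None else dict(rows=rows, cols=rows)
    out = []
    samples: dict[tuple, list] = {}
    for d4 in (0.18, 0.12):
        res = _battery("closed_loop_default", n_seeds,
                       cx_gating_offset=d4, **size)
        for metric in ("speed", "freq"):
            vals = [r[metric] for r in res]
            samples[(d4, metric)] = vals
            out.append(_summary_row(f"d4={d4}", metric, vals))
    for metric in ("speed", "freq"):
        diff, sem, t, p, _ = wv.compare_conditions(
            samples[(0.12, metric)], samples[(0.18, metric)])
        out.append(dict(condition="lowered-vs-default", metric=metric,
                        mean=diff, sem=sem, n=n_seeds, t=t, p=p))
    return pd.DataFrame(out)


def connectivity_area(n_seeds: int = 5, rows: int | None = None,
          fractions=(0.25, 0.50, 0.75, 0.99)) -> pd.DataFrame:
    size = {} if rows is None else dict(rows=rows, cols=rows)
    out = []
    for frac in fractions:
        res = _battery("connectivity_sweep", n_seeds,
                       intra_fraction=frac, **size)
        out.append(_summary_row(f"intra={int(frac * 100)}%", "area_cells",
                                [r["area"] for r in res]))
    return pd.DataFrame(out)


def delay_duration(n_seeds: int = 3, rows: int | None = None,
          delays=(0.0, 2.0, 4.0, 6.0)) -> pd.DataFrame:
    size = {} if rows is None else dict(rows=rows, cols=rows)
    out = []
    for delay in delays:
        res = _battery("reduced_90pct_unconnected", n_seeds,
                       delay_ms=delay, **size)
        out.append(_summary_row(f"delay={delay:g}ms", "duration_ms",
                                [r["duration"] for r in res]))
    return pd.DataFrame(out)


def ei_frequency(n_seeds: int = 5, rows: int | None = None) -> pd.DataFrame:
    size = {} if rows is None else dict(rows=rows, cols=rows)
    out = []
    re1 = _battery("re_inhibition_x300", n_seeds, factor=1.0, **size)
    re300 = _battery("re_inhibition_x300", n_seeds, factor=300.0, **size)
    out.append(_summary_row("re-inh x1", "cx_freq_hz",
                            [r["freq"] for r in re1]))
    out.append(_summary_row("re-inh x300", "cx_freq_hz",
                            [r["freq"] for r in re300]))
    diff, sem, t, p, _ = wv.compare_conditions(
        [r["freq"] for r in re300], [r["freq"] for r in re1])
    out.append(dict(condition="x300-vs-x1", metric="cx_freq_hz",
                    mean=diff, sem=sem, n=n_seeds, t=t, p=p))
    tc1 = _battery("cx_tc_x10", n_seeds, factor=1.0, layer="tc", **size)
    tc10 = _battery("cx_tc_x10", n_seeds, factor=10.0, layer="tc", **size)
    out.append(_summary_row("cx->tc x1", "tc_freq_hz",
                            [r["freq"] for r in tc1]))
    out.append(_summary_row("cx->tc x10", "tc_freq_hz",
                            [r["freq"] for r in tc10]))
    return pd.DataFrame(out)


def cortical_excitation(n_seeds: int = 5, rows: int | None = None) -> pd.DataFrame:
    size = {} if rows is None else dict(rows=rows, cols=rows)
    out = []
    base = _battery("we_x2", n_seeds, factor=1.0, **size)
    doubled = _battery("we_x2", n_seeds, factor=2.0, **size)
    for metric in ("freq", "speed"):
        a = [r[metric] for r in doubled]
        b = [r[metric] for r in base]
        out.append(_summary_row("w_E x1", metric, b))
        out.append(_summary_row("w_E x2", metric, a))
        diff, sem, t, p, _ = wv.compare_conditions(a, b)
        out.append(dict(condition="x2-vs-x1", metric=metric, mean=diff,
                        sem=sem, n=n_seeds, t=t, p=p))
    return pd.DataFrame(out)


EXPERIMENTS = {
    "speed_ordering": speed_ordering,
    "threshold_effects": threshold_effects,
    "connectivity_area": connectivity_area,
    "delay_duration": delay_duration,
    "ei_frequency": ei_frequency,
    "cortical_excitation": cortical_excitation,
}


def run_experiment(name: str, n_seeds: int = 5,
                   rows: int | None = None, **kw: Any) -> pd.DataFrame:
    """Run one named protocol; returns its comparison table."""
    try:
        fn = EXPERIMENTS[name]
    except KeyError:
        raise KeyError(f"unknown experiment {name!r}; "
                       f"known: {sorted(EXPERIMENTS)}") from None
    return fn(n_seeds=n_seeds, rows=rows, **kw)
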