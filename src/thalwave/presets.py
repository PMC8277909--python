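"""Named scenario presets.

Each preset reconstructs one published simulation condition as a
:class:`~thalwave.model.SimulationConfig`: open vs closed loop, clustered
cortices, transmission-delay sweeps, unconnected-node wave steering,
spiral induction by an inhibition drop, and the E/I manipulation
scenarios.  Presets accept keyword overrides (``rows``, ``cols``,
``duration``, ``seed``, ...) so the same scenario can run at reduced
lattice sizes for tests.
"""

from __future__ import annotations

from typing import Any, Callable

from .model import Modifier, SimulationConfig
from .topology import ClusterSpec

__all__ = ["preset_catalog", "make_config"]


def _cfg(preset: str, **kw: Any) -> SimulationConfig:
    return SimulationConfig(preset=preset, **kw)


def _open_loop(**kw) -> SimulationConfig:
    """Open loop: no cortical feedback, 99% E, ~99% intracortical.

    Both the cortex and the relay layer are seeded so each subsystem
    launches its own wave (the thalamus is autonomous without feedback).
    """
    base = dict(kind="three_layer", intra_fraction=0.99, e_fraction=0.99,
                closed_loop=False, sigma=0.0, duration=300.0,
                triggers=(("cx", "center"), ("tc", "center")))
    base.update(kw)
    return _cfg("open_loop", **base)


def _closed_loop_deterministic(**kw) -> SimulationConfig:
    base = dict(kind="three_layer", intra_fraction=0.99, e_fraction=0.99,
                closed_loop=True, sigma=0.0, duration=400.0,
                triggers=(("cx", "center"),))
    base.update(kw)
    return _cfg("closed_loop_deterministic", **base)


def _closed_loop_default(**kw) -> SimulationConfig:
    base = dict(kind="three_layer", intra_fraction=0.99, e_fraction=0.8,
                closed_loop=True, duration=400.0,
                triggers=(("cx", "center"),))
    base.update(kw)
    return _cfg("closed_loop_default", **base)


def _connectivity_sweep(intra_fraction: float = 0.5, **kw) -> SimulationConfig:
    """Isolated cortex at a configurable intracortical fraction."""
    base = dict(kind="cortex_only", e_fraction=0.8, duration=300.0,
                triggers=(("cx", "center"),))
    base.update(kw)
    return _cfg("connectivity_sweep", intra_fraction=intra_fraction, **base)


def _clustered_25_90(**kw) -> SimulationConfig:
    rows = kw.get("rows", 60)
    cols = kw.get("cols", 60)
    r0, c0 = rows // 3, cols // 3
    cluster = ClusterSpec(
        regions=((r0, r0 + rows // 3, c0, c0 + cols // 3),),
        intra_fraction=0.90, overall_fraction=0.25,
    )
    base = dict(kind="three_layer", e_fraction=0.8, duration=400.0,
                cluster=cluster,
                triggers=(("cx", (rows // 2, cols // 2)),))
    base.update(kw)
    return _cfg("clustered_25_90", **base)


def _two_cluster_regions(rows: int, cols: int):
    h = max(rows // 4, 2)
    w = max(cols // 4, 2)
    top = (rows // 8, rows // 8 + h, cols // 8, cols // 8 + w)
    bottom = (rows - rows // 8 - h, rows - rows // 8,
              cols - cols // 8 - w, cols - cols // 8)
    return top, bottom


def _two_cluster(closed: bool, **kw) -> SimulationConfig:
    rows = kw.get("rows", 60)
    cols = kw.get("cols", 60)
    top, bottom = _two_cluster_regions(rows, cols)
    cluster = ClusterSpec(regions=(top, bottom), intra_fraction=0.99,
                          overall_fraction=0.31)
    trig = ((top[0] + top[1]) // 2, (top[2] + top[3]) // 2)
    base = dict(e_fraction=0.8, duration=400.0, cluster=cluster,
                triggers=(("cx", trig),))
    base.update(kw)
    if closed:
        return _cfg("two_cluster_closed", kind="three_layer", **base)
    return _cfg("two_cluster_open", kind="cortex_only", **base)


def _reduced_base(**kw) -> dict:
    """Reduced two-layer model: fully connected all-E cortex plus TH."""
    base = dict(kind="reduced", intra_fraction=1.0, e_fraction=1.0,
                th_fraction=1.0, sigma=0.0, duration=200.0,
                delay_site="th_to_cx",
                triggers=(("cx", "center"),))
    base.update(kw)
    return base


def _reduced_delay(delay_ms: float = 4.0, **kw) -> SimulationConfig:
    return _cfg("reduced_delay", delay_ms=delay_ms, **_reduced_base(**kw))


def _reduced_90pct_unconnected(delay_ms: float = 4.0,
                               **kw) -> SimulationConfig:
    base = _reduced_base(connected_node_fraction=0.90, **kw)
    return _cfg("reduced_90pct_unconnected", delay_ms=delay_ms, **base)


def _node_preset(name: str, nodes_fn: Callable, delay_ms: float = 4.0,
                 **kw) -> SimulationConfig:
    rows = kw.get("rows", 60)
    cols = kw.get("cols", 60)
    nodes = tuple(nodes_fn(rows, cols))
    base = _reduced_base(unconnected_nodes=nodes, **kw)
    base["triggers"] = (("cx", "center"), ("cx", "unconnected"))
    return _cfg(name, delay_ms=delay_ms, **base)


def _node_inside_field(**kw) -> SimulationConfig:
    # uninhibited node near the centre of the cortical firing field
    return _node_preset(
        "node_inside_field",
        lambda r, c: [(r // 2 + 2, c // 2 + 2)], **kw)


def _node_at_edge(**kw) -> SimulationConfig:
    # uninhibited node at the edge of the firing field
    return _node_preset(
        "node_at_edge",
        lambda r, c: [(r // 4, c // 4)], **kw)


def _two_nodes(**kw) -> SimulationConfig:
    return _node_preset(
        "two_nodes",
        lambda r, c: [(r // 4, c // 4), (3 * r // 4, 3 * c // 4)], **kw)


def _node_line(**kw) -> SimulationConfig:
    def line(r, c):
        row = r // 2
        return [(row, j) for j in range(c // 4, 3 * c // 4)]
    cfg = _node_preset("node_line", line, **kw)
    # a temporary threshold block on half the line initiates a
    # unidirectional wave along it
    rows = cfg.rows
    cols = cfg.cols
    block = tuple((rows // 2, j) for j in range(cols // 2, 3 * cols // 4))
    return _cfg(
        "node_line",
        **{**_as_kwargs(cfg),
           "modifiers": (Modifier("threshold_block", t=0.0, t_off=10.0,
                                  cells=block),)},
    )


def _spiral_inhibition_drop(**kw) -> SimulationConfig:
    base = _reduced_base(**kw)
    base["modifiers"] = (
        Modifier("weight_scale", t=28.0, factors=(("w_th_cx", 0.1),)),
    )
    return _cfg("spiral_inhibition_drop", delay_ms=4.0, **base)


def _re_inhibition_x300(factor: float = 300.0, **kw) -> SimulationConfig:
    """RE inhibition scaling (nearly full cortex, 90% excitatory)."""
    base = dict(kind="three_layer", intra_fraction=1.0, e_fraction=0.9,
                duration=400.0, triggers=(("cx", "center"),),
                weight_factors=(("w_re_cx", factor),))
    base.update(kw)
    return _cfg("re_inhibition_x300", **base)


def _cx_tc_x10(factor: float = 10.0, **kw) -> SimulationConfig:
    base = dict(kind="three_layer", intra_fraction=1.0, e_fraction=0.9,
                duration=400.0, triggers=(("cx", "center"),),
                weight_factors=(("w_cx_tc", factor),))
    base.update(kw)
    return _cfg("cx_tc_x10", **base)


def _we_x2(factor: float = 2.0, **kw) -> SimulationConfig:
    base = dict(kind="three_layer", intra_fraction=0.99, e_fraction=0.8,
                duration=400.0, triggers=(("cx", "center"),),
                weight_factors=(("w_e", factor),))
    base.update(kw)
    return _cfg("we_x2", **base)


def _big_array_80(**kw) -> SimulationConfig:
    base = dict(rows=80, cols=80)
    base.update(kw)
    return _reduced_90pct_unconnected(**base)


_CATALOG: dict[str, Callable[..., SimulationConfig]] = {
    "open_loop": _open_loop,
    "closed_loop_deterministic": _closed_loop_deterministic,
    "closed_loop_default": _closed_loop_default,
    "connectivity_sweep": _connectivity_sweep,
    "clustered_25_90": _clustered_25_90,
    "two_cluster_open": lambda **kw: _two_cluster(False, **kw),
    "two_cluster_closed": lambda **kw: _two_cluster(True, **kw),
    "reduced_delay": _reduced_delay,
    "reduced_90pct_unconnected": _reduced_90pct_unconnected,
    "node_inside_field": _node_inside_field,
    "node_at_edge": _node_at_edge,
    "two_nodes": _two_nodes,
    "node_line": _node_line,
    "spiral_inhibition_drop": _spiral_inhibition_drop,
    "re_inhibition_x300": _re_inhibition_x300,
    "cx_tc_x10": _cx_tc_x10,
    "we_x2": _we_x2,
    "big_array_80": _big_array_80,
}


def preset_catalog() -> list[str]:
    """Names of every built-in scenario."""
    return sorted(_CATALOG)


def make_config(preset: str, **overrides: Any) -> SimulationConfig:
    """Instantiate a preset, applying keyword overrides."""
    try:
        fn = _CATALOG[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; known: {preset_catalog()}"
        ) from None
    return fn(**overrides)


def _as_kwargs(cfg: SimulationConfig) -> dict:
    from dataclasses import fields

    return {f.name: getattr(cfg, f.name) for f in fields(cfg)
            if f.name != "preset"}
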