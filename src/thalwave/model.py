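"""Coupled-lattice integration of the thalamocortical network.

Three model kinds are supported:

* ``three_layer`` -- relay (TC), reticular (RE) and cortical (CX) sheets
  coupled in a closed loop: the cortex drives both thalamic layers
  through a shared 1% sparse feedback matrix, 10% of thalamic cells
  project back to the cortex, and the RE/TC pair recruits itself through
  reciprocal nearest-neighbour inhibition and rebound spiking (the
  lurching-wave machinery).
* ``reduced`` -- a single inhibitory thalamic layer (TH) with lateral
  excitation plus a fully connected all-excitatory cortex; thalamic
  inhibition reaches the cortex after a configurable transmission delay
  carried by rebound-element chains.
* ``cortex_only`` -- the isolated cortical sheet.

Integration is explicit Euler-Maruyama with dt = 0.01 ms by default
(the stiffest damping in the model, a1 + a2*eta with eta near its
saturated maximum, approaches 150/ms, so 0.01 ms keeps the explicit
update well inside its stability region);
cortical cells receive Gaussian noise as a diffusion term (sigma *
sqrt(dt) per step).  A one-cell ring of boundary cells is made
permanently unexcitable by a large gating-nullcline offset, so waves are
absorbed rather than reflected at the lattice edge.
"""

from __future__ import annotations

import hashlib
import time as _time
from dataclasses import dataclass, field, replace, asdict
from typing import Any

import numpy as np
import scipy.sparse as sp

from . import coupling as cpl
from . import phaseplane as pp
from .params import (CX_REDUCED, CX_THREE_LAYER, ExcitableParams,
                     TC_THREE_LAYER, TH_REDUCED, WeightSet)
from .topology import (ClusterSpec, LatticeSpec, assign_ei, build_C_TH,
                       build_lattice4, connectivity_fraction,
                       random_cell_mask, thin_clustered, thin_uniform)

__all__ = [
    "SimulationConfig",
    "Modifier",
    "Trajectory",
    "Wiring",
    "Simulation",
    "run",
    "BOUNDARY_ETA_RAISE",
]

#: gating-nullcline raise (in eta units) applied to absorbing boundary cells
BOUNDARY_ETA_RAISE = 6.0


@dataclass(frozen=True)
class Modifier:
    """A scheduled change of the running model.

    kinds:
      ``weight_scale``   -- at ``t``, multiply named weights by ``factors``
      ``threshold_block``-- raise the gating bias of ``cells`` (cortex)
                            by ``bias`` during [t, t_off]
      ``delay_switch``   -- at ``t``, set the transmission delay to
                            ``delay_ms``
      ``stimulus``       -- add ``amplitude`` to the cortical drive of
                            ``cells`` during [t, t_off]
      ``identity``       -- no-op (placebo for schedule tests)
    """

    kind: str
    t: float = 0.0
    t_off: float = np.inf
    factors: tuple[tuple[str, float], ...] = ()
    cells: tuple[tuple[int, int], ...] = ()
    bias: float = BOUNDARY_ETA_RAISE
    delay_ms: float = 0.0
    amplitude: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to rebuild and rerun one simulation exactly."""

    preset: str = "custom"
    kind: str = "three_layer"          # three_layer | reduced | cortex_only
    rows: int = 60
    cols: int = 60
    dt: float = 0.01                   # ms
    duration: float = 400.0            # ms
    record_every: float = 2.0          # ms
    seed: int = 0
    boundary_width: int = 1
    # wiring
    intra_fraction: float = 0.99
    cluster: ClusterSpec | None = None
    e_fraction: float = 0.8
    m_fraction: float = 0.01           # CX -> TC/RE feedback density
    w_fraction: float = 0.10           # TC/RE -> CX density
    th_fraction: float = 0.10          # TH -> CX density (reduced)
    connected_node_fraction: float = 1.0
    unconnected_nodes: tuple[tuple[int, int], ...] | None = None
    closed_loop: bool = True
    weights: WeightSet | None = None
    weight_factors: tuple[tuple[str, float], ...] = ()
    sigma: float | None = None         # None -> WeightSet default
    # transmission delay (rebound-element chains)
    delay_ms: float = 0.0
    delay_site: str = "th_to_cx"       # th_to_cx | re_to_cx | cx_to_thalamus
    # initial triggers: (layer, "center" | (row, col))
    triggers: tuple[tuple[str, Any], ...] = (("cx", "center"),)
    trigger_v: float = 1.5
    modifiers: tuple[Modifier, ...] = ()
    # system-threshold knob: override the cortical gating offset d4
    # (lowering it lowers the gating nullcline and the activation
    # threshold of every cortical cell)
    cx_gating_offset: float | None = None
    # numerical-stability saturation of each layer's net input.  The
    # reduced model's divergent gathers are multiplicative in the
    # postsynaptic voltage with row sums in the hundreds, so synchronous
    # volleys would violate the explicit integrator's stability limit;
    # the topographic three-layer projections are bounded by
    # construction and need no saturation.  None selects per-model:
    # +-60 for the reduced model, unbounded otherwise.
    input_clamp: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.dt > 0.05:
            raise ValueError("dt must be in (0, 0.05] ms")
        n = self.record_every / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("record_every must be a multiple of dt")
        if self.kind not in ("three_layer", "reduced", "cortex_only"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.delay_ms % 2 != 0:
            raise ValueError("delay_ms must be a multiple of 2 ms")

    @property
    def lattice(self) -> LatticeSpec:
        return LatticeSpec(self.rows, self.cols)

    def resolved_weights(self) -> WeightSet:
        w = self.weights
        if w is None:
            w = (WeightSet.reduced() if self.kind == "reduced"
                 else WeightSet.three_layer())
        if self.weight_factors:
            w = w.scaled(**dict(self.weight_factors))
        if not self.closed_loop:
            w = replace(w, w_cx_tc=0.0, w_cx_re=0.0)
        if self.sigma is not None:
            w = replace(w, sigma=self.sigma)
        return w


@dataclass
class Wiring:
    """Realised connectivity of one run.

    The neighbour structures (``x_sparse`` intracortical adjacency,
    ``c_th`` cross-layer 4-neighbour map) are true sparse-matrix
    gathers.  The three-layer "x% of neurons project" structures are
    binary per-cell gate vectors applied topographically (one-to-one
    between co-registered lattices): ``m_gate`` for the 1% cortical
    feedback to both thalamic layers and ``w_gate`` for the 10%
    thalamic projection to the cortex.  The reduced model's
    ``w_sparse_th`` is a divergent 10% random matrix whose rows gather
    thalamic inhibition per cortical cell (unconnected nodes have their
    rows zeroed); ``cx_to_th`` is the unmasked reciprocal driving the
    thalamus.
    """

    lattice: LatticeSpec
    x_sparse: sp.csr_matrix | None = None
    c_th: sp.csr_matrix | None = None
    m_gate: np.ndarray | None = None
    w_gate: np.ndarray | None = None
    w_sparse_th: sp.csr_matrix | None = None     # TH -> CX rows (masked)
    w_sparse_th_t: sp.csr_matrix | None = None   # its transpose
    cx_to_th: sp.csr_matrix | None = None        # reciprocal, unmasked
    cx_to_th_t: sp.csr_matrix | None = None
    e_mask: np.ndarray | None = None
    i_mask: np.ndarray | None = None

    # projections in the form the coupling operators consume
    @property
    def m_proj(self):
        return self.m_gate

    @property
    def w_proj(self):
        return self.w_gate

    @property
    def th_proj_in(self):
        # divergent thalamic inhibition onto the cortex (rows gather TH)
        if self.w_sparse_th is None:
            return None
        return (self.w_sparse_th, self.w_sparse_th_t)

    @property
    def th_proj_out(self):
        # reciprocal cortical drive onto the thalamus
        if self.cx_to_th is None:
            return None
        return (self.cx_to_th, self.cx_to_th_t)

    @property
    def ei_labels(self) -> np.ndarray:
        return self.e_mask.astype(bool)

    def audit(self) -> dict:
        """Connection-count audit for the run manifest."""
        out: dict[str, Any] = {"n_per_layer": self.lattice.n}
        if self.x_sparse is not None:
            out["intra_fraction"] = connectivity_fraction(
                self.x_sparse, self.lattice.full_edge_count())
        for name in ("m_gate", "w_gate"):
            g = getattr(self, name)
            if g is not None:
                out[name + "_ones"] = int(g.sum())
        if self.w_sparse_th is not None:
            out["w_th_ones"] = int(self.w_sparse_th.nnz)
            rows = np.diff(self.w_sparse_th.indptr)
            out["th_connected_rows"] = int((rows > 0).sum())
        if self.e_mask is not None:
            out["excitatory"] = int(self.e_mask.sum())
        return out

    def hashes(self) -> dict:
        def hm(mat):
            coo = sp.coo_matrix(mat)
            order = np.lexsort((coo.col, coo.row))
            return hashlib.sha256(
                np.column_stack([coo.row[order], coo.col[order]])
                .astype(np.int64).tobytes()
            ).hexdigest()[:16]

        def hv(vec):
            return hashlib.sha256(
                vec.astype(np.int8).tobytes()).hexdigest()[:16]

        out = {}
        for name in ("x_sparse", "w_sparse_th"):
            mat = getattr(self, name)
            if mat is not None:
                out[name] = hm(mat)
        for name in ("m_gate", "w_gate", "e_mask"):
            g = getattr(self, name)
            if g is not None:
                out[name] = hv(g)
        return out


def build_wiring(config: SimulationConfig,
                 rng: np.random.Generator) -> Wiring:
    """Realise every binary structure the configured model needs."""
    lat = config.lattice
    n = lat.n
    wiring = Wiring(lattice=lat)

    # intracortical adjacency
    full = build_lattice4(lat)
    if config.cluster is not None:
        x = thin_clustered(full, lat, config.cluster, rng)
    elif config.intra_fraction < 1.0:
        x = thin_uniform(full, config.intra_fraction, rng,
                         reference_edges=lat.full_edge_count())
    else:
        x = full
    wiring.x_sparse = x

    labels = assign_ei(n, config.e_fraction, rng)
    wiring.e_mask = labels.astype(float)
    wiring.i_mask = (~labels).astype(float)

    if config.kind == "three_layer":
        wiring.c_th = build_C_TH(lat)
        wiring.m_gate = random_cell_mask(n, config.m_fraction, rng)
        wiring.w_gate = random_cell_mask(n, config.w_fraction, rng)
    elif config.kind == "reduced":
        wiring.c_th = build_C_TH(lat)
        # divergent long-range thalamic inhibition: each cortical cell
        # gathers a random 10% of thalamic cells; the cortical drive to
        # the thalamus is the reciprocal (transposed) structure
        from .topology import random_bipartite

        wth = random_bipartite(n, n, config.th_fraction, rng)
        # unconnected nodes: chosen cortical cells receive no thalamic
        # inhibition (their rows are zeroed; the reciprocal projection
        # to the thalamus is untouched, never added to)
        off: list[int] = []
        if config.unconnected_nodes:
            off = [lat.index(r, c) for r, c in config.unconnected_nodes]
        elif config.connected_node_fraction < 1.0:
            k = int(round((1 - config.connected_node_fraction) * n))
            off = list(rng.choice(n, size=k, replace=False))
        wiring.cx_to_th = sp.csr_matrix(wth.T)   # reciprocal, unmasked
        wiring.cx_to_th_t = sp.csr_matrix(wth)
        if off:
            wth = wth.tolil()
            for i in off:
                wth.rows[i] = []
                wth.data[i] = []
            wth = sp.csr_matrix(wth)
        wiring.w_sparse_th = wth
        wiring.w_sparse_th_t = sp.csr_matrix(wth.T)
    return wiring


@dataclass
class Trajectory:
    """Recorded movies (voltage frames per layer) plus run manifest."""

    movies: dict[str, np.ndarray]      # layer -> (T, rows, cols) float32
    frame_dt: float
    config: SimulationConfig
    manifest: dict

    @property
    def times(self) -> np.ndarray:
        t = next(iter(self.movies.values())).shape[0]
        return np.arange(t) * self.frame_dt


class _Layer:
    """State fields of one lattice layer."""

    def __init__(self, name: str, params: ExcitableParams, n: int,
                 boundary: np.ndarray):
        self.name = name
        self.params = params
        rest = None
        for q in pp.find_equilibria(params, 0.0):
            if pp.stability(params, q)[1]:
                rest = q
                break
        if rest is None:
            raise RuntimeError(f"layer {name}: no stable rest state")
        self.v = np.full(n, rest[0])
        self.eta = np.full(n, rest[1])
        self.s = np.zeros(n)
        # absorbing high-threshold boundary: permanent gating bias that
        # raises the nullcline by BOUNDARY_ETA_RAISE eta-units, plus a
        # floor keeping the ring's gating variable at its raised rest
        # (sustained inhibition would otherwise slowly walk it down into
        # rebound territory)
        leak = params.c1 if params.gating_kind == "type3" else params.d1
        self.eta_bias = np.where(boundary, BOUNDARY_ETA_RAISE * leak, 0.0)
        self.eta_floor = np.where(boundary, rest[1] + BOUNDARY_ETA_RAISE,
                                  -np.inf)
        self.rest = rest

    def euler(self, drive: np.ndarray, dt: float) -> None:
        p = self.params
        dv = pp.voltage_rate(self.v, self.eta, p, drive)
        de = pp.gating_rate(self.v, self.eta, p) + self.eta_bias
        ds = pp.synapse_rate(self.v, self.s, p)
        self.v = self.v + dt * dv
        self.eta = np.maximum(self.eta + dt * de, self.eta_floor)
        self.s = self.s + dt * ds


class Simulation:
    """One configured model instance ready to integrate."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        lat = config.lattice
        n = lat.n
        ss = np.random.SeedSequence(config.seed)
        wiring_ss, noise_ss = ss.spawn(2)
        self.wiring = build_wiring(config,
                                   np.random.default_rng(wiring_ss))
        self.noise_rng = np.random.default_rng(noise_ss)
        self.weights = config.resolved_weights()

        boundary = np.zeros((lat.rows, lat.cols), dtype=bool)
        bw = config.boundary_width
        if bw > 0:
            boundary[:bw, :] = boundary[-bw:, :] = True
            boundary[:, :bw] = boundary[:, -bw:] = True
        self.boundary = boundary.ravel()

        cx_params = CX_REDUCED if config.kind == "reduced" \
            else CX_THREE_LAYER
        if config.cx_gating_offset is not None:
            cx_params = cx_params.with_gating_offset(config.cx_gating_offset)
        self.layers: dict[str, _Layer] = {}
        if config.kind == "three_layer":
            self.layers["tc"] = _Layer("tc", TC_THREE_LAYER, n, self.boundary)
            self.layers["re"] = _Layer("re", TC_THREE_LAYER, n, self.boundary)
            self.layers["cx"] = _Layer("cx", cx_params, n, self.boundary)
        elif config.kind == "reduced":
            self.layers["cx"] = _Layer("cx", cx_params, n, self.boundary)
            self.layers["th"] = _Layer("th", TH_REDUCED, n, self.boundary)
        else:
            self.layers["cx"] = _Layer("cx", cx_params, n, self.boundary)

        # transmission-delay chains
        self.chain: cpl.DelayChain | None = None
        if config.delay_ms > 0:
            self.chain = cpl.DelayChain(int(config.delay_ms // 2), n,
                                        i_p=self.weights.i_p)

        # scheduled state
        self._threshold_blocks: list[Modifier] = []
        self._stimuli: list[Modifier] = []
        self._pending = sorted(
            [m for m in config.modifiers],
            key=lambda m: m.t,
        )
        self.t = 0.0
        self._apply_triggers()

    # -- setup ----------------------------------------------------------
    def _apply_triggers(self) -> None:
        lat = self.config.lattice
        for layer_name, where in self.config.triggers:
            if layer_name not in self.layers:
                continue
            if where == "center":
                cells = [(lat.rows // 2, lat.cols // 2)]
            elif where == "unconnected":
                if not self.config.unconnected_nodes:
                    continue
                cells = list(self.config.unconnected_nodes)
            else:
                cells = [where] if isinstance(where[0], int) else list(where)
            for r, c in cells:
                self.layers[layer_name].v[lat.index(r, c)] = \
                    self.config.trigger_v

    # -- modifiers ------------------------------------------------------
    def _service_modifiers(self) -> None:
        while self._pending and self._pending[0].t <= self.t + 1e-9:
            m = self._pending.pop(0)
            if m.kind == "weight_scale":
                self.weights = self.weights.scaled(**dict(m.factors))
            elif m.kind == "threshold_block":
                self._threshold_blocks.append(m)
                self._set_block(m, on=True)
            elif m.kind == "delay_switch":
                if self.chain is None:
                    self.chain = cpl.DelayChain(
                        int(m.delay_ms // 2), self.config.lattice.n,
                        i_p=self.weights.i_p)
                else:
                    self.chain.set_n_elements(int(m.delay_ms // 2))
            elif m.kind == "stimulus":
                self._stimuli.append(m)
            elif m.kind == "identity":
                pass
            else:
                raise ValueError(f"unknown modifier kind {m.kind!r}")
        for m in list(self._threshold_blocks):
            if self.t >= m.t_off:
                self._set_block(m, on=False)
                self._threshold_blocks.remove(m)
        self._stimuli = [m for m in self._stimuli if self.t < m.t_off]

    def _set_block(self, m: Modifier, on: bool) -> None:
        lat = self.config.lattice
        cx = self.layers["cx"]
        leak = (cx.params.c1 if cx.params.gating_kind == "type3"
                else cx.params.d1)
        delta = m.bias * leak if on else -m.bias * leak
        for r, c in m.cells:
            cx.eta_bias[lat.index(r, c)] += delta

    def _stimulus_field(self, n: int) -> np.ndarray | None:
        if not self._stimuli:
            return None
        lat = self.config.lattice
        out = np.zeros(n)
        for m in self._stimuli:
            if m.t <= self.t < m.t_off:
                for r, c in m.cells:
                    out[lat.index(r, c)] += m.amplitude
        return out

    # -- integration ----------------------------------------------------
    def step(self) -> None:
        """One Euler-Maruyama update of every layer (and delay chains)."""
        cfg = self.config
        w = self.weights
        dt = cfg.dt
        self._service_modifiers()
        n = cfg.lattice.n
        cx = self.layers["cx"]
        stim = self._stimulus_field(n)
        clamp = cfg.input_clamp
        if clamp is None:
            clamp = 60.0 if cfg.kind == "reduced" else np.inf

        def sat(x):
            if not np.isfinite(clamp):
                return x
            return np.clip(x, -clamp, clamp)

        if cfg.kind == "three_layer":
            tc, re = self.layers["tc"], self.layers["re"]
            conn = self.wiring
            r_eff = re.s
            c_eff = cx.s
            if self.chain is not None:
                if cfg.delay_site in ("re_to_cx", "th_to_cx"):
                    r_eff = self.chain.output(re.s)
                    chain_in = re.s
                else:  # cx_to_thalamus
                    c_eff = self.chain.output(cx.s)
                    chain_in = cx.s
            tc_in = cpl.tc_input(re.s, c_eff, tc.v, conn, w)
            re_in = cpl.re_input(tc.s, c_eff, re.v, conn, w)
            cx_in = cpl.cx_input(conn, w, cx.v, t_s=tc.s, r_s=r_eff,
                                 c_s=cx.s, components=(1, 2, 3, 4),
                                 stimulus=stim)
            if self.chain is not None:
                self.chain.step(chain_in, dt)
            tc.euler(sat(tc_in), dt)
            re.euler(sat(re_in), dt)
            cx.euler(sat(cx_in), dt)
        elif cfg.kind == "reduced":
            th = self.layers["th"]
            conn = self.wiring
            l_eff = th.s
            c_eff = cx.s
            if self.chain is not None:
                if cfg.delay_site == "cx_to_thalamus":
                    c_eff = self.chain.output(cx.s)
                    chain_in = cx.s
                else:  # th_to_cx (default thalamocortical delay)
                    l_eff = self.chain.output(th.s)
                    chain_in = th.s
            th_in = cpl.th_input_reduced(th.v, th.s, c_eff, conn, w)
            cx_in = cpl.cx_input(conn, w, cx.v, c_s=cx.s, l_s=l_eff,
                                 components=(3, 5), stimulus=stim)
            if self.chain is not None:
                self.chain.step(chain_in, dt)
            th.euler(sat(th_in), dt)
            cx.euler(sat(cx_in), dt)
        else:  # cortex_only
            conn = self.wiring
            cx_in = cpl.cx_input(conn, w, cx.v, c_s=cx.s,
                                 components=(3, 4), stimulus=stim)
            cx.euler(sat(cx_in), dt)

        if w.sigma > 0:
            cx.v = cx.v + w.mu * dt + w.sigma * np.sqrt(dt) * \
                self.noise_rng.standard_normal(n)
        self.t += dt
        if not np.isfinite(cx.v).all():
            bad = int(np.flatnonzero(~np.isfinite(cx.v))[0])
            raise FloatingPointError(
                f"non-finite cortical voltage at t={self.t:.3f} ms, "
                f"cell {bad}"
            )

    def run(self, progress: Any = None) -> Trajectory:
        """Integrate for the configured duration, recording voltage frames."""
        cfg = self.config
        lat = cfg.lattice
        stride = int(round(cfg.record_every / cfg.dt))
        n_steps = int(round(cfg.duration / cfg.dt))
        n_frames = n_steps // stride + 1
        movies = {
            name: np.empty((n_frames, lat.rows, lat.cols), dtype=np.float32)
            for name in self.layers
        }
        t0 = _time.perf_counter()
        frame = 0
        for name, layer in self.layers.items():
            movies[name][0] = layer.v.reshape(lat.rows, lat.cols)
        next_log = 10.0
        for k in range(n_steps):
            self.step()
            if (k + 1) % stride == 0:
                frame += 1
                for name, layer in self.layers.items():
                    movies[name][frame] = layer.v.reshape(lat.rows, lat.cols)
            if progress is not None and self.t >= next_log:
                progress(self.t)
                next_log += 10.0
        manifest = {
            "config": _config_dict(cfg),
            "wiring": self.wiring.audit(),
            "wiring_hashes": self.wiring.hashes(),
            "wall_time_s": round(_time.perf_counter() - t0, 3),
        }
        return Trajectory(movies=movies, frame_dt=cfg.record_every,
                          config=cfg, manifest=manifest)


def _config_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    if cfg.weights is not None:
        d["weights"] = asdict(cfg.weights)
    if cfg.cluster is not None:
        d["cluster"] = {"regions": list(map(list, cfg.cluster.regions)),
                        "intra_fraction": cfg.cluster.intra_fraction,
                        "overall_fraction": cfg.cluster.overall_fraction}
    d["modifiers"] = [asdict(m) for m in cfg.modifiers]
    return d


def run(config: SimulationConfig, progress: Any = None) -> Trajectory:
    """Build the configured model and integrate it."""
    return Simulation(config).run(progress=progress)
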