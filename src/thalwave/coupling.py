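"""Inter/intra-layer input fields and the fictitious-neuron delay chains.

Input operators follow the matrix-gather convention: a binary
connectivity row gathers the presynaptic synapse values of one
postsynaptic cell; no per-row normalisation is applied.  Every operator
is linear in each synaptic field (holding the voltage fields fixed) and
exactly zero when all presynaptic synapses vanish.

Transmission delays are not implemented as delay-differential equations:
a synaptic pulse is instead relayed through a chain of "fictitious"
type-3-like cells.  Each chain element receives the incoming pulse as an
inhibitory conductance, hyperpolarises, and emits a post-inhibitory
rebound spike whose wait time is calibrated to 2 ms; n elements in
series therefore delay a pulse by 2n ms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .params import ExcitableParams, TC_THREE_LAYER, WeightSet
from . import phaseplane as pp

__all__ = [
    "masked_matvec",
    "project",
    "silence_subthreshold",
    "tc_input",
    "re_input",
    "cx_input",
    "th_input_reduced",
    "DelayChain",
    "make_delay_chain",
    "calibrate_delay_element",
    "DelayCalibrationError",
]

#: Synapse values below this are treated as silent.  The synaptic
#: sigmoid H(v) never reaches exactly zero at rest (H ~ 1.6e-4 at the
#: relay rest voltage), and summed over hundreds of divergent sources
#: that resting leak would amount to a spurious tonic drive; cells are
#: therefore only transmitting while their output exceeds this cutoff,
#: three orders of magnitude below a spike's synaptic pulse.
ACTIVE_EPS = 1e-3


def masked_matvec(mat_t: sp.csr_matrix, x: np.ndarray) -> np.ndarray:
    """Compute ``mat @ x`` given the csr transpose, skipping silent cells.

    Synapse fields are near-zero outside spiking wavefronts, so gathering
    only active presynaptic columns (rows of the transpose) is much
    cheaper than a full product during quiet episodes.
    """
    idx = np.flatnonzero(x > ACTIVE_EPS)
    if idx.size == 0:
        return np.zeros(mat_t.shape[1])
    if idx.size > mat_t.shape[0] // 4:
        xa = np.where(x > ACTIVE_EPS, x, 0.0)
        return np.asarray(xa @ mat_t).ravel()
    return np.asarray(x[idx] @ mat_t[idx]).ravel()


# ---------------------------------------------------------------------------
# Input fields.  All fields are flat (n,) arrays over one lattice.
#
# A projection can be either a per-cell binary gate (1-D array: topographic
# one-to-one wiring restricted to a fraction of cells -- how the network
# realises the "x% of neurons project" sparsity structures) or a sparse
# matrix gather (given as a (mat, mat_transpose) pair, rows collecting
# presynaptic values with unnormalised sums).
# ---------------------------------------------------------------------------

def silence_subthreshold(s) -> np.ndarray:
    """Zero synapse values below the silent-synapse cutoff."""
    s = np.asarray(s, dtype=float)
    return np.where(s > ACTIVE_EPS, s, 0.0)


def project(proj, x: np.ndarray) -> np.ndarray:
    """Apply one projection (gate vector, matrix pair, or plain matrix)."""
    x = np.asarray(x)
    if proj is None:
        return np.zeros_like(x)
    if isinstance(proj, np.ndarray):
        return proj * x
    if isinstance(proj, tuple):
        return masked_matvec(proj[1], x)
    return np.asarray(proj @ x).ravel()


def tc_input(r_s, c_s, t_v, conn, w: WeightSet) -> np.ndarray:
    """Drive onto the thalamic relay layer.

    ``-w_re_tc * (C_TH @ R_s) * (T_v + i_p) + w_cx_tc * (M . C_s) * T_v``:
    reticular inhibition gathered from the four surrounding RE cells plus
    sparse excitatory cortical feedback (M = 1% gate at defaults).
    """
    r_s, c_s, t_v = map(np.asarray, (r_s, c_s, t_v))
    if not (r_s.shape == c_s.shape == t_v.shape):
        raise ValueError("field shapes differ")
    r_s = silence_subthreshold(r_s)
    c_s = silence_subthreshold(c_s)
    inh = conn.c_th @ r_s
    exc = project(conn.m_proj, c_s)
    return -w.w_re_tc * inh * (t_v + w.i_p) + w.w_cx_tc * exc * t_v


def re_input(t_s, c_s, r_v, conn, w: WeightSet,
             floor: float | None = None) -> np.ndarray:
    """Drive onto the reticular layer, clamped below at ``floor``.

    Relay excitation is reciprocal and elementwise (``T_s * R_v``);
    cortical feedback arrives through the shared feedback structure M.
    The net input saturates at a configurable minimum to prevent
    numerical instabilities.
    """
    t_s, c_s, r_v = map(np.asarray, (t_s, c_s, r_v))
    if floor is None:
        floor = w.re_input_floor
    if not np.isfinite(floor):
        raise ValueError("floor must be finite")
    t_s = silence_subthreshold(t_s)
    c_s = silence_subthreshold(c_s)
    drive = w.w_tc_re * t_s * r_v + w.w_cx_re * project(conn.m_proj, c_s) \
        * r_v
    return np.maximum(drive, floor)


def cx_input(
    conn,
    w: WeightSet,
    c_v,
    t_s=None,
    r_s=None,
    c_s=None,
    l_s=None,
    components: Sequence[int] = (1, 2, 3, 4),
    stimulus=None,
) -> np.ndarray:
    """Deterministic part of the cortical drive (components 1-5).

    Components: (1) relay excitation, (2) reticular inhibition, (3)/(4)
    excitatory/inhibitory intracortical drive split by presynaptic E/I
    label, (5) reduced-model thalamic inhibition.  The Gaussian noise
    component (6) is a diffusion term and is added by the integrator, not
    here.  ``stimulus`` adds an external signed field.
    """
    c_v = np.asarray(c_v)
    n = c_v.size
    gain = w.k_n / np.sqrt(n)
    out = np.zeros(n)
    comps = set(components)
    if 1 in comps:
        out += w.w_tc_cx * project(conn.w_proj,
                                   silence_subthreshold(t_s)) * c_v
    if 2 in comps:
        out -= w.w_re_cx * project(conn.w_proj,
                                   silence_subthreshold(r_s)) \
            * (c_v + w.i_p)
    if 3 in comps or 4 in comps:
        c_s = silence_subthreshold(c_s)
        if 3 in comps:
            out += w.w_e * gain * (conn.x_sparse @ (c_s * conn.e_mask))
        if 4 in comps:
            out -= w.w_i * gain * (conn.x_sparse @ (c_s * conn.i_mask))
    if 5 in comps:
        if getattr(conn, "th_proj_in", None) is None:
            raise ValueError(
                "component 5 requires the reduced-model thalamic layer"
            )
        out -= w.w_th_cx * project(conn.th_proj_in,
                                   silence_subthreshold(l_s)) \
            * (c_v + w.i_p)
    if stimulus is not None:
        out += np.asarray(stimulus)
    return out


def th_input_reduced(l_v, l_s, c_s, conn, w: WeightSet) -> np.ndarray:
    """Drive onto the reduced-model thalamic layer.

    Lateral excitation gathered over the four nearest neighbours plus
    sparse cortical drive, both gated multiplicatively by the local
    voltage: ``w_th * (C_TH @ L_s) * L_v + w_cx_th * (W_TH . C_s) * L_v``.
    """
    l_v, l_s, c_s = map(np.asarray, (l_v, l_s, c_s))
    if not (l_v.shape == l_s.shape == c_s.shape):
        raise ValueError("field shapes differ")
    l_s = silence_subthreshold(l_s)
    c_s = silence_subthreshold(c_s)
    lateral = conn.c_th @ l_s
    cortical = project(conn.th_proj_out, c_s)
    return (w.w_th * lateral + w.w_cx_th * cortical) * l_v


# ---------------------------------------------------------------------------
# Delay chains.
# ---------------------------------------------------------------------------

class DelayCalibrationError(RuntimeError):
    """No gating time scale reaches the target rebound wait."""


@dataclass
class _Element:
    """One fictitious rebound cell per lattice site."""

    v: np.ndarray
    eta: np.ndarray
    s: np.ndarray


class DelayChain:
    """Series of rebound elements delaying a synaptic field by 2 ms each.

    ``n_elements = 0`` is the identity.  Each element is a lattice of
    type-3-like cells with a calibrated gating time scale; an incoming
    synaptic pulse acts as an inhibitory conductance ``-w_inh * s_in *
    (v + i_p)``, and the post-inhibitory rebound re-emits the pulse 2 ms
    later.  Pulse count is conserved: one input spike yields one output
    spike per element pass.
    """

    def __init__(self, n_elements: int, n_cells: int,
                 params: ExcitableParams | None = None,
                 w_inh: float = 3.0, i_p: float = 5.0):
        if n_elements < 0:
            raise ValueError("n_elements must be >= 0")
        if params is not None:
            self._params = (params, params)
        else:
            # the first element sees network-cell pulses; deeper elements
            # see the output pulses of the element ahead of them, so each
            # stage is calibrated against the pulse family it receives
            self._params = (calibrate_delay_element(pulse_family="network"),
                            calibrate_delay_element(pulse_family="chain"))
        self.w_inh = w_inh
        self.i_p = i_p
        self.n_cells = n_cells
        self.elements: list[_Element] = []
        self.set_n_elements(n_elements)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def params(self) -> ExcitableParams:
        return self._params[0]

    def _stage_params(self, stage: int) -> ExcitableParams:
        return self._params[0] if stage == 0 else self._params[1]

    def _rest_element(self, stage: int) -> _Element:
        v0, e0 = _rest_state(self._stage_params(stage))
        n = self.n_cells
        return _Element(np.full(n, v0), np.full(n, e0), np.zeros(n))

    def set_n_elements(self, n: int) -> None:
        """Grow (fresh rest elements) or shrink the chain in place.

        Used by the mid-run delay-switch modifier (e.g. 4 ms -> 6 ms).
        """
        while len(self.elements) < n:
            self.elements.append(self._rest_element(len(self.elements)))
        del self.elements[n:]

    def step(self, s_in: np.ndarray, dt: float) -> np.ndarray:
        """Advance every element one Euler step; return the delayed field."""
        x = np.asarray(s_in)
        for stage, el in enumerate(self.elements):
            p = self._stage_params(stage)
            drive = -self.w_inh * x * (el.v + self.i_p)
            dv = pp.voltage_rate(el.v, el.eta, p, drive)
            de = pp.gating_rate(el.v, el.eta, p)
            ds = pp.synapse_rate(el.v, el.s, p)
            el.v = el.v + dt * dv
            el.eta = el.eta + dt * de
            el.s = el.s + dt * ds
            x = el.s
        return x

    def output(self, s_in: np.ndarray) -> np.ndarray:
        """Current delayed field without stepping (identity when empty)."""
        return self.elements[-1].s if self.elements else np.asarray(s_in)


def make_delay_chain(n_elements: int, n_cells: int,
                     **kw) -> DelayChain:
    """Build a chain of ``n_elements`` calibrated rebound elements."""
    return DelayChain(n_elements, n_cells, **kw)


# -- calibration ------------------------------------------------------------

def _rest_state(p: ExcitableParams) -> tuple[float, float]:
    for q in pp.find_equilibria(p, 0.0):
        if pp.stability(p, q)[1]:
            return q
    raise DelayCalibrationError("element parameters have no stable rest")


def _canonical_pulse(dt: float, duration: float = 12.0):
    """Synaptic pulse of one full type-3 spike (the network's pulse shape)."""
    p = TC_THREE_LAYER
    v0, e0 = _rest_state(p)
    t, v, eta, s = pp.simulate_single(
        p, drive=lambda tt: 3.0 if 1.0 <= tt < 2.0 else 0.0, dt=dt,
        duration=duration, state=pp.NeuronState(v=v0, eta=e0, s=0.0),
    )
    return t, s


def _element_response(kappa: float, t: np.ndarray, pulse: np.ndarray,
                      dt: float, base: ExcitableParams,
                      w_inh: float, i_p: float):
    p = base.with_gating_rate_scale(kappa)
    try:
        v0, e0 = _rest_state(p)
    except DelayCalibrationError:
        return None
    n = len(t)
    v, eta, s = v0, e0, 0.0
    out = np.empty(n)
    for k in range(n):
        drive = -w_inh * pulse[k] * (v + i_p)
        dv = pp.voltage_rate(v, eta, p, drive)
        de = pp.gating_rate(v, eta, p)
        ds = pp.synapse_rate(v, s, p)
        v += dt * dv
        eta += dt * de
        s += dt * ds
        out[k] = s
    return out


def _measure_lag(kappa, t, pulse, dt, base, w_inh, i_p):
    out = _element_response(kappa, t, pulse, dt, base, w_inh, i_p)
    if out is None or out.max() < 0.5:
        return np.inf, None
    return t[int(np.argmax(out))] - t[int(np.argmax(pulse))], out

_CAL_CACHE: dict = {}


def calibrate_delay_element(
    target_ms: float = 2.0,
    tol_ms: float = 0.05,
    base: ExcitableParams = TC_THREE_LAYER,
    w_inh: float = 3.0,
    i_p: float = 5.0,
    dt: float = 0.002,
    pulse_family: str = "network",
) -> ExcitableParams:
    """Tune one rebound element's gating time scale to a 2 ms wait.

    Bisects the gating rate factor (slower gating -> shallower gating
    undershoot during the inhibitory pulse -> longer crawl past the fold
    -> longer rebound wait) until the input-peak-to-output-peak lag hits
    ``target_ms``.  ``pulse_family`` selects the calibration input:
    ``"network"`` uses the synaptic pulse of an ordinary type-3 network
    cell (what the first chain element receives), ``"chain"`` the emitted
    pulse of a calibrated element itself (what deeper elements receive),
    found by fixed-point iteration.  Deterministic; results are cached
    per configuration.
    """
    key = (target_ms, base, w_inh, i_p, dt, pulse_family)
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    if pulse_family not in ("network", "chain"):
        raise ValueError("pulse_family must be 'network' or 'chain'")

    horizon = max(6.0 * target_ms, 12.0)
    t, pulse = _canonical_pulse(dt, duration=horizon)

    def solve(t, pulse):
        # lag decreases with kappa; bracket then bisect
        lo, hi = 0.02, 3.0
        lag_lo, _ = _measure_lag(lo, t, pulse, dt, base, w_inh, i_p)
        lag_hi, _ = _measure_lag(hi, t, pulse, dt, base, w_inh, i_p)
        if not (lag_hi <= target_ms):
            raise DelayCalibrationError(
                f"fastest gating gives lag {lag_hi:.3f} ms > target"
            )
        if lag_lo < target_ms:
            raise DelayCalibrationError(
                f"slowest gating gives lag {lag_lo:.3f} ms < target"
            )
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            lag, _ = _measure_lag(mid, t, pulse, dt, base, w_inh, i_p)
            if lag > target_ms:
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-12:
                break
        return 0.5 * (lo + hi)

    kappa = solve(t, pulse)
    if pulse_family == "chain":
        # fixed point: recalibrate on the element's own emitted pulse
        for _ in range(2):
            lag, out = _measure_lag(kappa, t, pulse, dt, base, w_inh, i_p)
            pulse = out
            kappa = solve(t, pulse)
    lag, _ = _measure_lag(kappa, t, pulse, dt, base, w_inh, i_p)
    if abs(lag - target_ms) > tol_ms:
        raise DelayCalibrationError(
            f"calibration converged to lag {lag:.3f} ms, "
            f"outside {target_ms} +- {tol_ms} ms"
        )
    params = base.with_gating_rate_scale(kappa)
    _CAL_CACHE[key] = params
    return params


def measure_chain_lag(n_elements: int, dt: float = 0.002,
                      params: ExcitableParams | None = None) -> float:
    """Drive an n-element chain with one pulse; return peak-to-peak lag."""
    horizon = 6.0 + 4.0 * max(n_elements, 1)
    t, pulse = _canonical_pulse(dt, duration=horizon)
    chain = DelayChain(n_elements, n_cells=1, params=params)
    out = np.empty(len(t))
    for k in range(len(t)):
        out[k] = chain.step(np.array([pulse[k]]), dt)[0]
    if n_elements == 0:
        return 0.0
    if out.max() < 0.5:
        raise DelayCalibrationError("chain emitted no pulse")
    return float(t[int(np.argmax(out))] - t[int(np.argmax(pulse))])
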