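"""Single-cell dynamics, phase-plane analysis and threshold measurement.

The (v, eta) phase plane of each cell carries an inverted-N voltage
nullcline and a gating nullcline (a line through the origin for type-3
cells, a bounded sigmoid for type-1 cells).  Their intersection ``m`` is
the equilibrium; the local minimum ``p`` of the voltage nullcline is a
fold point.  Raising the drive ``r`` lifts the voltage nullcline, moving
``m`` toward ``p``; when they meet, stability is lost and the cell starts
self-sustained oscillation.  The Euclidean distance ``||m - p||`` is the
cell's activation threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .params import ExcitableParams, H_CENTER, H_GAIN

__all__ = [
    "NeuronState",
    "PhasePlaneReport",
    "NoStableEquilibrium",
    "voltage_rate",
    "gating_rate",
    "synapse_rate",
    "synaptic_activation",
    "nullclines",
    "v_nullcline",
    "gating_nullcline",
    "fold_point",
    "find_equilibria",
    "stability",
    "activation_threshold",
    "phase_plane_report",
    "simulate_single",
    "spike_times",
    "SPIKE_LEVEL",
]

#: Upward-crossing level on v used for spike detection.  The synaptic
#: sigmoid is centred at v = 0.1 while spikes excurse to v ~ 5, so any
#: level well above 0.1 and well below the peak works; 0.5 is used
#: throughout.
SPIKE_LEVEL = 0.5


class NoStableEquilibrium(RuntimeError):
    """Raised when the threshold is requested past the fold bifurcation."""


@dataclass
class NeuronState:
    """State triple of one cell: voltage, gating variable, synapse."""

    v: float = 0.0
    eta: float = 0.0
    s: float = 0.0


# ---------------------------------------------------------------------------
# Rate functions.  All accept scalars or ndarrays in v/eta/s.
# ---------------------------------------------------------------------------

def voltage_rate(v, eta, p: ExcitableParams, r=0.0):
    """dv/dt = -(a1 + a2*eta)*v + a3*v^2/(a4 + v^2) + a5 + r."""
    return -(p.a1 + p.a2 * eta) * v + p.a3 * v * v / (p.a4 + v * v) + p.a5 + r


def gating_rate(v, eta, p: ExcitableParams):
    """deta/dt for either gating kind.

    The type-1 activation d2*v^3/(d3 + v^3) approximates a sigmoid on
    v >= 0 but has a spurious pole at v = -d3^(1/3); the voltage is
    rectified inside the activation (v_+ = max(v, 0)) so hyperpolarised
    cells simply contribute zero activation, leaving all v >= 0
    behaviour untouched.
    """
    if p.gating_kind == "type3":
        return -p.c1 * eta + p.c2 * v
    vp = np.maximum(v, 0.0)
    v3 = vp * vp * vp
    return -p.d1 * eta + p.d2 * v3 / (p.d3 + v3) + p.d4


def synaptic_activation(v, p: ExcitableParams | None = None):
    """H(v) = 0.5*(1 + tanh(120*(v - 0.1))), the spike-to-synapse sigmoid."""
    return 0.5 * (1.0 + np.tanh(H_GAIN * (v - H_CENTER)))


def synapse_rate(v, s, p: ExcitableParams):
    """ds/dt = (H(v) - s) / (t1*(s1 - H(v)))."""
    h = synaptic_activation(v)
    return (h - s) / (p.t1 * (p.s1 - h))


# ---------------------------------------------------------------------------
# Nullclines and equilibria.
# ---------------------------------------------------------------------------

def v_nullcline(v, p: ExcitableParams, r=0.0):
    """eta(v) on the voltage nullcline; singular at v = 0.

    Solving dv/dt = 0 for eta gives
    ``eta = (-a1*v + a3*v^2/(a4+v^2) + a5 + r) / (a2*v)``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v == 0):
        raise ZeroDivisionError("the v-nullcline is singular at v = 0")
    return (-p.a1 * v + p.a3 * v * v / (p.a4 + v * v) + p.a5 + r) / (p.a2 * v)


def gating_nullcline(v, p: ExcitableParams):
    """eta(v) on the gating nullcline."""
    v = np.asarray(v, dtype=float)
    if p.gating_kind == "type3":
        return (p.c2 / p.c1) * v
    vp = np.maximum(v, 0.0)
    v3 = vp * vp * vp
    return (p.d2 * v3 / (p.d3 + v3) + p.d4) / p.d1


def nullclines(p: ExcitableParams, r=0.0, v_grid=None):
    """Sample both nullclines on a voltage grid.

    Returns ``(v, eta_vnull, eta_gnull)``; the grid excludes v = 0 where
    the voltage nullcline is singular.
    """
    if v_grid is None:
        v_grid = np.linspace(1e-3, 3.0, 1000)
    v_grid = np.asarray(v_grid, dtype=float)
    v_grid = v_grid[v_grid != 0.0]
    return v_grid, v_nullcline(v_grid, p, r), gating_nullcline(v_grid, p)


def fold_point(p: ExcitableParams, r=0.0, v_range=(1e-4, 1.0)):
    """Local minimum ``p`` of the voltage nullcline for v > 0.

    Located by a dense grid scan followed by bounded scalar minimisation.
    """
    v = np.geomspace(v_range[0], v_range[1], 4000)
    eta = v_nullcline(v, p, r)
    i = int(np.argmin(eta))
    lo = v[max(i - 1, 0)]
    hi = v[min(i + 1, len(v) - 1)]
    res = optimize.minimize_scalar(
        lambda x: float(v_nullcline(x, p, r)), bounds=(lo, hi),
        method="bounded", options={"xatol": 1e-12},
    )
    return float(res.x), float(res.fun)


def find_equilibria(
    p: ExcitableParams,
    r=0.0,
    v_box=(-2.0, 3.0),
    n_scan: int = 4000,
    tol: float = 1e-9,
) -> list[tuple[float, float]]:
    """All nullcline intersections with v in ``v_box``.

    Scans the sign of ``eta_vnull - eta_gnull`` on a dense grid (v = 0
    excluded, where no equilibrium can sit as long as a5 + r != 0) and
    polishes each bracket with a 2-D Newton solve.  Each returned point
    satisfies both rates to ``tol``.
    """
    out: list[tuple[float, float]] = []
    for lo, hi in ((v_box[0], -1e-6), (1e-6, v_box[1])):
        if hi <= lo:
            continue
        v = np.linspace(lo, hi, n_scan)
        diff = v_nullcline(v, p, r) - gating_nullcline(v, p)
        sign = np.sign(diff)
        idx = np.flatnonzero(sign[:-1] * sign[1:] < 0)
        for i in idx:
            vr = optimize.brentq(
                lambda x: float(v_nullcline(x, p, r) - gating_nullcline(x, p)),
                v[i], v[i + 1], xtol=1e-14,
            )
            er = float(gating_nullcline(vr, p))
            sol = optimize.fsolve(
                lambda z: [voltage_rate(z[0], z[1], p, r),
                           gating_rate(z[0], z[1], p)],
                [vr, er], full_output=False, xtol=1e-13,
            )
            vr, er = float(sol[0]), float(sol[1])
            if abs(voltage_rate(vr, er, p, r)) < tol and \
               abs(gating_rate(vr, er, p)) < tol:
                if not any(abs(vr - v0) < 1e-7 for v0, _ in out):
                    out.append((vr, er))
    out.sort()
    return out


def jacobian(p: ExcitableParams, v: float, eta: float, r=0.0) -> np.ndarray:
    """Analytic 2x2 Jacobian of (voltage_rate, gating_rate)."""
    dfv = -(p.a1 + p.a2 * eta) + p.a3 * 2 * v * p.a4 / (p.a4 + v * v) ** 2
    dfe = -p.a2 * v
    if p.gating_kind == "type3":
        dgv, dge = p.c2, -p.c1
    else:
        vp = max(v, 0.0)
        dgv = p.d2 * 3 * vp * vp * p.d3 / (p.d3 + vp ** 3) ** 2
        dge = -p.d1
    return np.array([[dfv, dfe], [dgv, dge]])


def stability(p: ExcitableParams, point, r=0.0, tol: float = 1e-6):
    """Eigenvalues of the Jacobian at an equilibrium, plus a stable flag.

    Warns (via the returned residual) if the point is not an equilibrium
    to tolerance; stability means both real parts negative.
    """
    v, eta = float(point[0]), float(point[1])
    resid = max(abs(voltage_rate(v, eta, p, r)), abs(gating_rate(v, eta, p)))
    if resid > tol:
        import warnings

        warnings.warn(
            f"point ({v:.4g}, {eta:.4g}) is not an equilibrium "
            f"(residual {resid:.2g})", stacklevel=2,
        )
    eig = np.linalg.eigvals(jacobian(p, v, eta, r))
    return eig, bool(np.all(eig.real < 0))


def activation_threshold(p: ExcitableParams, r=0.0) -> float:
    """Distance ||m - p|| between the stable equilibrium and the fold.

    Raises :class:`NoStableEquilibrium` past the fold bifurcation, where
    the cell oscillates and no threshold is defined.
    """
    vp, ep = fold_point(p, r)
    stable = []
    for eq in find_equilibria(p, r):
        _, ok = stability(p, eq, r)
        if ok:
            stable.append(eq)
    if not stable:
        raise NoStableEquilibrium(
            "no stable equilibrium; the cell is past the bifurcation and "
            "oscillates"
        )
    vm, em = min(stable, key=lambda q: (q[0] - vp) ** 2 + (q[1] - ep) ** 2)
    return float(np.hypot(vm - vp, em - ep))


@dataclass
class PhasePlaneReport:
    """Full phase-plane summary of one cell class at drive r."""

    params: ExcitableParams
    r: float
    v_grid: np.ndarray
    eta_vnull: np.ndarray
    eta_gnull: np.ndarray
    equilibria: list[tuple[float, float]]
    eigenvalues: list[np.ndarray]
    stable: list[bool]
    fold: tuple[float, float]
    threshold: float | None

    def to_csv(self, nullcline_path, equilibria_path) -> None:
        """Write the nullclines and a one-row-per-equilibrium table."""
        with open(nullcline_path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["v", "eta_vnull", "eta_gnull"])
            for row in zip(self.v_grid, self.eta_vnull, self.eta_gnull):
                w.writerow([f"{x:.8g}" for x in row])
        with open(equilibria_path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["v", "eta", "eig1_re", "eig1_im", "eig2_re",
                        "eig2_im", "stable", "fold_v", "fold_eta",
                        "threshold"])
            thr = "" if self.threshold is None else f"{self.threshold:.8g}"
            for (v, e), eig, st in zip(self.equilibria, self.eigenvalues,
                                       self.stable):
                w.writerow([
                    f"{v:.8g}", f"{e:.8g}",
                    f"{eig[0].real:.8g}", f"{eig[0].imag:.8g}",
                    f"{eig[1].real:.8g}", f"{eig[1].imag:.8g}",
                    int(st), f"{self.fold[0]:.8g}", f"{self.fold[1]:.8g}",
                    thr,
                ])


def phase_plane_report(p: ExcitableParams, r=0.0,
                       v_grid=None) -> PhasePlaneReport:
    """Assemble nullclines, equilibria, eigenvalues and threshold."""
    v, evn, egn = nullclines(p, r, v_grid)
    eqs = find_equilibria(p, r)
    eigs, flags = [], []
    for q in eqs:
        e, ok = stability(p, q, r)
        eigs.append(e)
        flags.append(ok)
    try:
        thr = activation_threshold(p, r)
    except NoStableEquilibrium:
        thr = None
    return PhasePlaneReport(p, float(r), v, evn, egn, eqs, eigs, flags,
                            fold_point(p, r), thr)


# ---------------------------------------------------------------------------
# Single-cell simulation.
# ---------------------------------------------------------------------------

def simulate_single(
    p: ExcitableParams,
    drive: Callable[[float], float] | float = 0.0,
    dt: float = 0.005,
    duration: float = 200.0,
    state: NeuronState | None = None,
    multiplicative_inhibition: Callable[[float], float] | None = None,
    i_p: float = 5.0,
):
    """Forward-Euler integration of one cell under a drive protocol.

    ``drive`` is an additive input r(t) (a constant or a callable of time
    in ms).  ``multiplicative_inhibition`` optionally supplies a
    synaptic-conductance-style pulse g(t) applied as ``-g*(v + i_p)`` --
    the form thalamic inhibition takes in the network -- used to probe
    post-inhibitory rebound.

    Returns ``(t, v, eta, s)`` arrays sampled every step.  Aborts on
    non-finite state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    v = np.empty(n + 1)
    eta = np.empty(n + 1)
    s = np.empty(n + 1)
    if state is None:
        eqs = find_equilibria(p, 0.0)
        stable = [q for q in eqs if stability(p, q)[1]]
        v0, e0 = stable[0] if stable else (0.0, 0.0)
        state = NeuronState(v=v0, eta=e0, s=0.0)
    v[0], eta[0], s[0] = state.v, state.eta, state.s
    r_of_t = drive if callable(drive) else (lambda _t, _r=float(drive): _r)
    for k in range(n):
        tk = t[k]
        r = r_of_t(tk)
        if multiplicative_inhibition is not None:
            r = r - multiplicative_inhibition(tk) * (v[k] + i_p)
        dv = voltage_rate(v[k], eta[k], p, r)
        de = gating_rate(v[k], eta[k], p)
        ds = synapse_rate(v[k], s[k], p)
        v[k + 1] = v[k] + dt * dv
        eta[k + 1] = eta[k] + dt * de
        s[k + 1] = s[k] + dt * ds
        if not (np.isfinite(v[k + 1]) and np.isfinite(eta[k + 1])):
            raise FloatingPointError(
                f"non-finite state at t = {t[k + 1]:.3f} ms"
            )
    return t, v, eta, s


def spike_times(t: np.ndarray, v: np.ndarray,
                level: float = SPIKE_LEVEL,
                refractory_samples: int = 1) -> np.ndarray:
    """Times of upward crossings of ``level`` on a voltage trace."""
    above = v >= level
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if refractory_samples > 1 and len(crossings) > 1:
        keep = [crossings[0]]
        for c in crossings[1:]:
            if c - keep[-1] > refractory_samples:
                keep.append(c)
        crossings = np.array(keep)
    return t[crossings]
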