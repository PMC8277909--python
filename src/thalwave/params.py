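"""Parameter sets for the two-state excitable neuron and the network couplings.

Every cell in the network is a two-state excitable unit: a fast voltage
``v`` with self-amplifying positive feedback and a slow gating variable
``eta`` providing negative feedback, plus a synaptic output ``s`` that
relays spikes to postsynaptic cells.  Two gating variants are used:

* ``type3`` -- linear gating nullcline through the origin.  These cells
  fire a single spike to a sustained step, show post-inhibitory rebound,
  and oscillate at a nearly input-independent frequency (thalamic relay
  and reticular cells).
* ``type1`` -- sigmoid gating nullcline with an additive offset.  These
  cells can fire at arbitrarily low rates near threshold and their
  frequency grows with drive (cortical cells).

The model time unit is 1 ms: all coefficients below are per-millisecond,
which makes the quoted transmission delays and the 2-ms frame interval of
recorded movies directly comparable with the state equations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

__all__ = [
    "ExcitableParams",
    "WeightSet",
    "TC_THREE_LAYER",
    "RE_THREE_LAYER",
    "CX_THREE_LAYER",
    "CX_REDUCED",
    "TH_REDUCED",
    "named_params",
    "H_GAIN",
    "H_CENTER",
]

# Synaptic activation sigmoid H(v) = 0.5*(1 + tanh(H_GAIN*(v - H_CENTER))).
H_GAIN = 120.0
H_CENTER = 0.1

GatingKind = Literal["type1", "type3"]


@dataclass(frozen=True)
class ExcitableParams:
    """Coefficients of one excitable cell class.

    Voltage equation::

        dv/dt = -(a1 + a2*eta)*v + a3*v**2/(a4 + v**2) + a5 + r

    Gating equation, by kind::

        type3:  deta/dt = -c1*eta + c2*v
        type1:  deta/dt = -d1*eta + d2*v**3/(d3 + v**3) + d4

    Synapse equation::

        ds/dt = (H(v) - s) / (t1*(s1 - H(v)))

    with H(v) a steep sigmoid centred at v = 0.1.  ``s1 > 1`` keeps the
    denominator positive for H in [0, 1].
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    gating_kind: GatingKind
    # type-3 gating (linear nullcline eta = (c2/c1) v)
    c1: float = 0.0
    c2: float = 0.0
    # type-1 gating (sigmoid nullcline with offset d4)
    d1: float = 0.0
    d2: float = 0.0
    d3: float = 0.0
    d4: float = 0.0
    # synapse
    s1: float = 10.0
    t1: float = 0.01

    def __post_init__(self) -> None:
        if self.a4 <= 0:
            raise ValueError("a4 must be positive")
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.s1 <= 1:
            raise ValueError("s1 must exceed 1 so s1 - H(v) stays positive")
        if self.gating_kind not in ("type1", "type3"):
            raise ValueError(f"unknown gating_kind {self.gating_kind!r}")
        if self.gating_kind == "type3" and self.c1 <= 0:
            raise ValueError("type3 gating requires c1 > 0")
        if self.gating_kind == "type1" and (self.d1 <= 0 or self.d3 <= 0):
            raise ValueError("type1 gating requires d1 > 0 and d3 > 0")

    # -- threshold-modulation knobs -------------------------------------
    def with_gating_slope_scale(self, factor: float) -> "ExcitableParams":
        """Scale the slope c2/c1 of the type-3 gating nullcline.

        Lowering the slope raises the gating nullcline intersection and
        lowers the activation threshold of a type-3 cell.
        """
        if self.gating_kind != "type3":
            raise ValueError("slope scaling applies to type3 gating only")
        return replace(self, c2=self.c2 * factor)

    def with_gating_offset(self, d4: float) -> "ExcitableParams":
        """Set the additive offset d4 of the type-1 gating equation.

        The offset sets the height of the gating nullcline; lowering it
        lowers the nullcline and with it the activation threshold.
        """
        if self.gating_kind != "type1":
            raise ValueError("offset shift applies to type1 gating only")
        return replace(self, d4=d4)

    def with_gating_rate_scale(self, factor: float) -> "ExcitableParams":
        """Scale the gating time constant (c1 and c2 together).

        The nullcline (and hence the phase-plane geometry) is unchanged;
        only the speed of the slow variable changes.  Used to calibrate
        the rebound wait of the fictitious delay neurons.
        """
        if self.gating_kind != "type3":
            raise ValueError("rate scaling implemented for type3 gating")
        return replace(self, c1=self.c1 * factor, c2=self.c2 * factor)


# ---------------------------------------------------------------------------
# Named parameter sets.
#
# Three-layer model: TC and RE are type-3 with identical coefficients; the
# cortex is type-1.  Reduced two-layer model: the cortex keeps the same
# voltage equation with retuned gating, and a single inhibitory thalamic
# layer (TH) replaces the TC/RE pair.
# ---------------------------------------------------------------------------

_A_VOLT = dict(a1=0.167, a2=16.67, a3=167.0, a4=1.2, a5=1.47)

TC_THREE_LAYER = ExcitableParams(
    **_A_VOLT, gating_kind="type3", c1=0.05, c2=1.5, s1=10.0, t1=0.01
)

# Reticular cells share the relay-cell dynamics (both are type-3).
RE_THREE_LAYER = TC_THREE_LAYER

CX_THREE_LAYER = ExcitableParams(
    **_A_VOLT, gating_kind="type1", d1=0.09, d2=0.6, d3=0.3, d4=0.18,
    s1=10.0, t1=0.01,
)

CX_REDUCED = ExcitableParams(
    **_A_VOLT, gating_kind="type1", d1=0.3, d2=2.0, d3=0.3, d4=0.6,
    s1=10.0, t1=0.01,
)

# The reduced-model TH layer is type-3 with a faster gating time constant
# (c1 = 0.2, i.e. a 5 ms gating time scale).  The gating-nullcline slope is
# kept at the three-layer value c2/c1 = 30: a slope anywhere below ~8.3
# would place the only equilibrium on the excited branch of the voltage
# nullcline, making the layer latch into a permanently depolarised state
# instead of remaining excitable at rest (see docs/methods.md).
TH_REDUCED = ExcitableParams(
    **_A_VOLT, gating_kind="type3", c1=0.2, c2=6.0, s1=10.0, t1=0.01
)

_NAMED = {
    "tc_table1": TC_THREE_LAYER,
    "re_table1": RE_THREE_LAYER,
    "cx_table1": CX_THREE_LAYER,
    "cx_table2": CX_REDUCED,
    "th_table2": TH_REDUCED,
}


def named_params(name: str) -> ExcitableParams:
    """Look up a cell class by its conventional name.

    Known names: ``tc_table1``, ``re_table1``, ``cx_table1`` (three-layer
    model) and ``cx_table2``, ``th_table2`` (reduced model).
    """
    try:
        return _NAMED[name]
    except KeyError:
        raise KeyError(
            f"unknown parameter set {name!r}; known: {sorted(_NAMED)}"
        ) from None


@dataclass(frozen=True)
class WeightSet:
    """All inter/intra-layer coupling weights (dimensionless).

    ``i_p`` shifts the driving-force term of inhibitory synapses so they
    keep pulling even when the postsynaptic voltage sits near zero;
    ``k_n / sqrt(N)`` normalises intracortical drive by lattice size.
    ``mu``/``sigma`` parametrise the Gaussian noise drive to cortical
    cells (entered as a diffusion term by the integrator).
    """

    # three-layer couplings
    w_re_tc: float = 3.0
    w_tc_re: float = 12.0
    w_re_cx: float = 0.02
    w_tc_cx: float = 25.0
    w_cx_tc: float = 0.75
    w_cx_re: float = 7.5
    # intracortical
    w_e: float = 3.0
    w_i: float = 6.0
    k_n: float = 16.2
    i_p: float = 5.0
    # noise (cortical cells only)
    mu: float = 0.0
    sigma: float = 0.1
    # reduced-model couplings
    w_th_cx: float = 7.0
    w_cx_th: float = 1.0
    w_th: float = 15.0
    # floor for the net reticular input (numerical-stability clamp)
    re_input_floor: float = -60.0

    @classmethod
    def three_layer(cls, **overrides: float) -> "WeightSet":
        """Default weights of the three-layer (TC/RE/CX) model."""
        return cls(**overrides)

    @classmethod
    def reduced(cls, **overrides: float) -> "WeightSet":
        """Default weights of the reduced two-layer (TH/CX) model."""
        base = dict(k_n=9.72, w_e=6.0, w_i=6.0, w_th_cx=7.0, w_cx_th=1.0,
                    w_th=15.0)
        base.update(overrides)
        return cls(**base)

    def scaled(self, **factors: float) -> "WeightSet":
        """Return a copy with named weights scaled multiplicatively.

        ``WeightSet().scaled(w_re_cx=300)`` multiplies the RE->CX weight
        by 300.  Used by the scenario presets (inhibition x300, CX->TC
        x10, w_E x2, ...).
        """
        changes = {}
        for name, factor in factors.items():
            if not hasattr(self, name):
                raise AttributeError(f"no weight named {name!r}")
            changes[name] = getattr(self, name) * factor
        return replace(self, **changes)
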