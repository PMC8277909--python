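# Model and methods

## The model

`thalwave` simulates a two-dimensional thalamocortical network built
from two-state excitable units. Every cell carries a fast voltage `v`
with self-amplifying positive feedback, a slow gating variable `eta`
providing negative feedback, and a synaptic output `s`:

    dv/dt   = -(a1 + a2*eta)*v + a3*v^2/(a4 + v^2) + a5 + I(t)
    ds/dt   = (H(v) - s) / (t1*(s1 - H(v))),   H(v) = (1 + tanh(120*(v - 0.1)))/2

with two gating variants:

    type-3:  deta/dt = -c1*eta + c2*v                      (linear nullcline)
    type-1:  deta/dt = -d1*eta + d2*v+^3/(d3 + v+^3) + d4  (sigmoid nullcline)

Type-3 cells (thalamic relay TC, reticular RE, and the reduced model's
inhibitory thalamic layer TH) fire one spike to a sustained step, show
post-inhibitory rebound, and oscillate at a nearly input-independent
frequency once destabilised. Type-1 cells (cortex CX) can fire at
arbitrarily low rates near onset with a drive-dependent rate. The model
time unit is 1 ms; all coefficients are per-ms. With the default
coefficients a single calibration anchors this choice: the natural
rebound wait of a type-3 cell is ~2 ms, matching the transmission-delay
element design below.

Three network kinds exist:

* **three_layer** — TC, RE and CX sheets (default 60x60 each, 10,800
  cells). CX is wired on a 4-neighbour lattice (`X_sparse`, thinnable
  uniformly or into dense clusters), with 80% excitatory / 20%
  inhibitory cells by exact count. RE↔TC recruit each other through the
  4-nearest-neighbour cross map `C_TH` (RE inhibits the four
  surrounding TC cells; each TC excites its co-registered RE), the
  machinery of the thalamic lurching wave. 10% of thalamic cells
  project one-to-one to the cortex (excitatory from TC, weakly
  inhibitory from RE, shared gate), and 1% of cortical cells project
  back to both thalamic layers (shared gate), closing the loop.
* **reduced** — a fully connected all-excitatory cortex plus a single
  inhibitory thalamic layer TH with lateral excitation through `C_TH`.
  TH↔CX coupling is divergent: each cortical cell gathers a random 10%
  of thalamic cells (`W_sparse_TH` rows) and the reciprocal transpose
  drives the thalamus. "Unconnected nodes" zero chosen rows only, so
  those cortical cells receive no thalamic inhibition while still
  driving the thalamus.
* **cortex_only** — the isolated cortical sheet.

Inhibitory synapses act through a driving-force term `-(v + i_p)` with
`i_p = 5`; excitatory cross-layer terms are multiplicative in the
postsynaptic voltage, exactly as the input equations are written.

### Topographic gates vs divergent gathers

The fraction-based structures are realised in two deliberately
different ways. In the three-layer model the "x% of neurons project"
structures are binary per-cell gates applied topographically: the
projection fraction is the fraction of *cells* that project one-to-one
between co-registered lattices. An all-to-all random-matrix gather with
unnormalised row sums is not an option there: the relay-to-cortex term
`w_TC_CX * (W @ T_s) * C_v` would put a positive coefficient of order
`25 * 0.1 * (active TC)` on the cortical voltage, while type-1 gating
saturates at `eta_max = (d2 + d4)/d1 = 8.67` so the maximum damping is
`a2 * eta_max ≈ 145`/ms — any synchronous thalamic volley would make
the cortex diverge. In the reduced model, by contrast, the long-range
*inhibition* from TH to CX is the point of the architecture (it carves
the "cortical firing field" that delayed inhibition imposes on a
spreading cortical wave), so there `W_sparse_TH` is a true divergent
10% random matrix. The divergent drive onto the thalamus is also what
makes the thalamic layer triggerable at all: with `w_CX_TH = 1` a
single topographic partner pulse adds a multiplicative growth rate of
~1/ms against a resting relaxation rate of ~14/ms and can never fire
the cell.

### Numerical scheme

Explicit Euler–Maruyama. Default `dt = 0.01 ms`: the stiffest local
damping, `a1 + a2*eta` with `eta` near its saturated maximum plus the
boundary offset, approaches 150/ms, and the explicit update requires
`dt * lambda < 2`; 0.01 ms leaves a greater than 30% margin everywhere
the state can reach. Cortical cells receive Gaussian noise as a
diffusion term `sigma * sqrt(dt) * N(0,1)` per step with
`(mu, sigma) = (0, 0.1)`; noise is applied to the cortex only and can
be switched off for deterministic scenarios.

Three saturations keep the multiplicative gathers inside the explicit
scheme's stability region, generalising the saturation the reticular
input equation itself prescribes:

* the net reticular input is floored at −60 (configurable);
* in the reduced model every layer's net input is clamped to ±60
  (configurable) — without it, a synchronous thalamic volley through
  the divergent matrix puts coefficients of several hundred per ms on
  the voltage. The three-layer model's topographic projections are
  bounded by construction and run unclamped (a blanket clamp there
  measurably distorts spike peaks and wave speeds);
* synaptic outputs below 1e-3 are treated as silent. The synaptic
  sigmoid never reaches exactly zero at rest (H ≈ 1.6e-4 at the relay
  rest voltage), and summed over hundreds of divergent sources that
  resting leak would otherwise act as a spurious tonic drive that
  shifts every fixed point.

The type-1 gating activation uses the rectified voltage `v+ = max(v,0)`
inside the cubic ratio. The printed form has a pole at
`v = -d3^(1/3) ≈ -0.67`; strongly inhibited cortical cells cross that
voltage and would diverge. Rectification leaves every non-negative
voltage untouched (the regime the sigmoid approximation was built for)
and makes hyperpolarised cells contribute zero activation.

Boundary handling: a one-cell ring is made permanently unexcitable by
raising its gating nullcline by 6 eta-units (an absorbing,
high-threshold boundary; waves terminate rather than reflect). The
ring's gating variable is additionally floored at its raised rest so
that sustained inhibition cannot slowly walk it into rebound range. The
+6 magnitude is chosen jointly with `dt`: it is far above the fold
(blocking all spiking) while keeping the ring's damping inside the
integrator's stability region.

Initial conditions: every cell starts at its stable rest; scenario
triggers displace chosen cells to `v = 1.5` (above threshold) at t = 0.
Frames are recorded every 2 ms (one frame per 2 ms of model time, the
temporal resolution all movie analysis assumes); raw `dt` states are
not stored.

### Transmission-delay chains

Delays are carried by chains of "fictitious" rebound cells rather than
delay-differential equations. Each element is a type-3-like cell whose
incoming pulse acts as an inhibitory conductance `-w*s_in*(v + i_p)`;
the post-inhibitory rebound re-emits the pulse. A one-parameter search
on the gating time scale (slower gating → shallower gating undershoot →
longer crawl past the fold → longer wait) calibrates the
input-peak-to-output-peak lag to 2.0 ms. The first chain element is
calibrated against the synaptic pulse of an ordinary network cell;
deeper elements against the pulse family they actually receive (an
element's own output, found by fixed-point iteration), so n elements
delay by 2n ms to within ~0.01 ms per stage. One limitation: an element
needs ~25 ms to recover its gating variable after a rebound, so pulse
trains faster than that lose pulses; the network's per-cell firing
intervals are normally longer.

## Parameters that matter

| parameter | default | role |
|---|---|---|
| `a1..a5` | 0.167, 16.67, 167, 1.2, 1.47 | voltage nullcline (inverted-N); shared by all cells |
| `c1, c2` (type-3) | 0.05, 1.5 | gating line slope 30, 20 ms time scale |
| `d1..d4` (type-1) | 0.09, 0.6, 0.3, 0.18 | cortical gating; `d4` is the system-threshold knob |
| `s1, t1` | 10, 0.01 | synapse gain/time scale (~0.1 ms decay) |
| `w_RE_TC, w_TC_RE` | 3, 12 | intra-thalamic loop (rebound machinery) |
| `w_TC_CX, w_RE_CX` | 25, 0.02 | thalamus → cortex (10% of cells) |
| `w_CX_TC, w_CX_RE` | 0.75, 7.5 | cortical feedback (1% of cells) |
| `w_E, w_I, k_n` | 3, 6, 16.2 | intracortical drive `w * k_n/sqrt(N)` per link |
| `i_p` | 5 | inhibitory driving-force offset |
| `mu, sigma` | 0, 0.1 | cortical noise (diffusion) |
| reduced: `k_n, w_E, w_TH_CX, w_CX_TH, w_TH` | 9.72, 6, 7, 1, 15 | two-layer variant |

Reduced-model cell classes: the cortical type-1 row (0.3, 2, 0.3, 0.6)
is exactly the three-layer row scaled uniformly in time by 10/3 with
the nullcline preserved. The thalamic type-3 row is implemented as
(0.2, 6.0) — the analogous uniform x4 time rescale with the slope-30
nullcline preserved. A literal slope-3 line cannot intersect the left
branch of this voltage nullcline (any slope below ~8.3 leaves only a
stable depolarised equilibrium near v ≈ 1.45 with the synapse fully
on), which would latch the whole layer at t = 0 and permanently
silence the cortex; the uniform rescale is the only reading consistent
with an excitable thalamic layer.

## Wave quantification

* **Segmentation**: suprathreshold mask at the midpoint between the
  resting voltage (movie median) and a robust spike peak (99.5th
  percentile of supra-rest samples; the raw maximum is dominated by a
  handful of drive-boosted cells); 4-connected components are patches.
* **Speed**: for each wavefront-boundary pixel of frame n+1, the
  Euclidean distance to the nearest boundary pixel of frame n, averaged
  and scaled by pixel pitch over frame interval. Calibration: 60 pixels
  spanning 24 mm (0.4 mm pitch) at one frame per 2 ms, i.e. 20 cm/s per
  pixel/frame. Array-edge pixels are not fronts. Movie-level averages
  exclude per-pixel displacements implying speeds above 300 cm/s (the
  top of the plausible mesoscopic range at this calibration): such
  jumps are de-novo nucleations of new patches elsewhere on the sheet,
  not propagation. The estimator is exact on rigid translating bands
  and biased low on strongly curved pixelated fronts (the radial
  fixture documents this; ring-radius growth from the area series
  recovers the expansion rate to ~1%).
* **Frequency**: periodogram peak of the spatial-mean interior voltage
  trace, zero bin excluded; flagged low-confidence below four cycles.
* **Lurch index**: along a kymograph scan line, the fraction of
  inter-frame intervals during which the leading-edge envelope of the
  suprathreshold region fails to advance, tracked from first detection
  until the front reaches the end of the line. Smooth constant-velocity
  fronts give ~0; a staircase advancing every k-th frame gives
  (k-1)/k. This operationalises "staggered in time".
* **Duration**: time between the first and last frame whose
  suprathreshold area exceeds a small cutoff (5 cells).
* **Direction**: angle of the mean centroid displacement (0° = +x,
  90° = up).
* **Comparison**: two-sided two-sample t-test over per-seed metric
  samples (degenerate zero-variance pairs flagged).

## What the synthetic fixtures do and do not show

The fixture generator renders geometric movies — translating planar
bands, expanding rings, rotating Archimedean spiral arms, staircase
("lurching") fronts, constants — with known speed, direction, period
and stall fraction, plus optional Gaussian pixel noise. They validate
the estimators independently of the simulator: recovery to 5% in speed,
one spectral bin in frequency, 5° in direction, and zero overlap of the
lurch index between the smooth and staircase families at default noise.
They are deliberately *not* dynamically realistic: they contain no
refractory tails, no multi-patch interference and no nucleation, so
passing fixture tests shows estimator correctness, not that the network
movies are easy to measure. Network movies in the fragmented
closed-loop regime mix propagation with nucleation, which is why the
movie-level speed average needs the propagation ceiling above.

## Problem sizes used

Correctness tests run at lattice sizes 3x3–30x30; end-to-end checks use
the study sizes: 60x60 for the closed-loop/open-loop conditions (400 ms
and 300 ms of model time), 30x30 with 3 seeds for the
connectivity–area and E/I-direction sweeps, and 40x40 with 3 seeds for
the reduced-model delay sweep. The reproduction protocols default to
5-seed batteries.

## Known limitations

* The default closed-loop operating point oscillates at ~22–30 Hz
  (seed-dependent), above the 10–20 Hz band the architecture is known
  to favour; cortical waves run at ~80–110 cm/s against thalamic
  activity at ~45 cm/s (ordering robust across seeds). The open-loop
  condition reproduces the canonical phenotypes cleanly (smooth
  cortical waves, thalamic lurching with lurch index ~0.8 vs 0 in the
  cortex). The global rhythm here is paced by the cortical recovery
  time (~1/d1), with thalamic re-triggering arriving as soon as the
  sheet recovers.
* In the reduced model the cortical wave crosses the sheet in a few
  milliseconds, faster than the 2–6 ms transmission delays, so delayed
  thalamic inhibition mostly arrives after the wave has already
  terminated at the absorbing boundary; the delay dependence of wave
  lifetime is correspondingly weak at the 40–60 pixel scales simulated.
* The divergent reduced-model thalamus fires as a near-synchronous
  volley once the cortical wave exceeds its threshold; spatially
  structured thalamic waves in that model require a locality of the
  cortex-to-thalamus drive that the architecture as specified does not
  pin down.
* Reticular bursting, laminar cortical structure, long-range
  intra-layer axons and conductance-based synapses are out of scope.
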