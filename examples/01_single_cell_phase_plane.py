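"""Phase-plane anatomy of one excitable cell.

Builds the thalamic relay (type-3) and cortical (type-1) cell classes,
locates their nullcline intersections, measures the activation
threshold (distance between the rest state m and the fold point p of
the voltage nullcline), and demonstrates the two firing signatures:
a single spike to a step for the relay cell, and a drive-dependent
firing rate for the cortical cell.
"""

import numpy as np

import thalwave as tw
from thalwave import phaseplane as pp

for name in ("tc_table1", "cx_table1"):
    p = tw.named_params(name)
    report = pp.phase_plane_report(p, r=0.0)
    print(f"\n{name} ({p.gating_kind}):")
    for (v, eta), stable in zip(report.equilibria, report.stable):
        tag = "stable" if stable else "unstable"
        print(f"  equilibrium ({v:+.4f}, {eta:+.4f})  [{tag}]")
    vp, ep = report.fold
    print(f"  fold point p = ({vp:.4f}, {ep:.4f})")
    print(f"  activation threshold ||m - p|| = {report.threshold:.4f}")

# a sustained step makes the relay cell fire exactly once
t, v, _, _ = pp.simulate_single(
    tw.TC_THREE_LAYER, drive=lambda tt: 2.0 if tt > 10 else 0.0,
    duration=200)
print("\nrelay cell, sustained step: "
      f"{len(pp.spike_times(t, v))} spike(s)")

# the cortical cell's rate grows with drive
for r in (0.8, 1.5, 3.0):
    t, v, _, _ = pp.simulate_single(tw.CX_THREE_LAYER, drive=r,
                                    duration=400)
    sp = pp.spike_times(t, v)
    rate = 1000.0 / np.mean(np.diff(sp)) if len(sp) > 2 else 0.0
    print(f"cortical cell, drive {r:.1f}: {rate:5.1f} Hz")
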