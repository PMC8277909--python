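"""Smooth cortical waves vs staggered thalamic lurching (open loop).

With the cortical feedback to the thalamus cut, each subsystem runs on
its own: a triggered relay cell starts the reticular/relay rebound
cycle, which crawls across the thalamic sheet in discrete jumps, while
the cortex sustains fast smooth waves.  The lurch index quantifies the
contrast: ~0 for a front that advances every frame, large for a front
that stalls between jumps.
"""

import thalwave as tw
from thalwave import waves as wv

cfg = tw.make_config("open_loop", rows=40, cols=40, duration=200.0, seed=1)
traj = tw.run(cfg)

row = cfg.rows // 2
for layer in ("cx", "tc"):
    movie = wv.ActivityMovie(traj.movies[layer], frame_dt=traj.frame_dt)
    lurch = wv.lurch_index(wv.kymograph(movie, row), traj.frame_dt)
    speed = wv.mean_wave_speed(movie)
    print(f"{layer}: lurch index {lurch:.2f}, "
          f"mean wave speed {speed:.0f} cm/s")

# Expected: the cortical lurch index is ~0 (smooth wave) and the
# thalamic one is large (staggered advance), with the cortical wave an
# order of magnitude faster -- the two canonical wave phenotypes.
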