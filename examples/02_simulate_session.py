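"""Simulate one mock neuron end to end: behavior, spikes, dF/F.

Generates a 10-minute virtual-track session, drives an inhomogeneous
Poisson neuron with a 2-bits/AP rate map, and synthesizes the gCaMP6f
fluorescence trace with recording noise.
"""

import numpy as np

import fluoinfo as fi
from fluoinfo import behavior as bhv

trace = fi.synth_behavior(600.0, seed=3)
mask = bhv.run_mask(trace)
v = bhv.speed_trace(trace)
print(f"session: {trace.duration/60:.0f} min, {trace.n_laps} laps, "
      f"mean running speed {v[mask.mask].mean():.1f} cm/s")

m = fi.optimize_ratemap(2.0, seed=5)
m.mean_rate = 1.0  # Hz
cif = fi.build_cif(m, trace)
train = fi.generate_spikes(cif, seed=6)
frames = fi.bin_to_frames(train)
print(f"neuron: {m.achieved_info_ap:.3f} bits/AP at {m.mean_rate} Hz -> "
      f"{train.n_spikes} spikes ({train.n_spikes/trace.duration:.2f} Hz realized)")

kernel = fi.get_kernel("gCaMP6f")
dff = fi.synth_fluorescence(train, kernel, noise_sd=0.15, seed=7)
print(f"gCaMP6f kernel: width {kernel.width:.3f} s, height {kernel.height} dF/F")
print(f"dF/F trace: {len(dff.values)} frames at 30 Hz, "
      f"peak {dff.values.max():.2f}, SD {dff.values.std():.3f} dF/F")
# The trace peak reflects stacked single-AP transients of height 0.19 on
# top of 0.15-SD white noise.
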