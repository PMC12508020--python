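"""Standard preprocessing: remap to one side, align, resample.

Mirroring all trajectories to the left side and translating starts to
(0, 0) makes trials comparable; time normalization (101 steps) supports
temporal analyses, length normalization (20 points) shape-based ones.
"""

import numpy as np

import reachtrace as rt

ds, _ = rt.generate(rt.SynthSpec(seed=7))
ds = rt.subset(ds, "correct == 1")          # drop error trials (~6.7%)
ds = rt.remap_symmetric(ds)                  # all endpoints to the left
ds = rt.align_start(ds)                      # starts at (0, 0)
ds = rt.time_normalize(ds, n_steps=101)
ds = rt.length_normalize(ds, n_points=20)

for name, arr in ds.representations.items():
    print(f"{name}: {arr.n_trials} trials x up to {arr.max_points} points")

ends = ds.get(rt.RAW).feature(rt.XPOS)
last = np.array([ends[i, ds.get(rt.RAW).valid_length[i] - 1]
                 for i in range(ds.n_trials)])
print("all endpoints on the left after remapping:", bool((last < 0).all()))
print("provenance records:", [p["operation"] for p in ds.provenance])

# tn_trajectories now gives every trial the same 101 time steps and
# ln_trajectories the same 20 arc-length-equidistant points; the raw
# representation is untouched.
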