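"""Generate a synthetic rodent-fMRI scan with known ground truth.

The phantom plants resting-state networks with band-limited timecourses on
a baseline image, adds linear drift, thermal noise, structured physiological
noise and motion spikes, and returns every planted quantity.
"""

import numpy as np

from boldqc import PhantomConfig, framewise_displacement, make_phantom

phantom = make_phantom(PhantomConfig(), seed=0)
fd = framewise_displacement(phantom.motion)

print(f"grid: {phantom.ts.grid.shape} voxels at {phantom.ts.grid.spacing[0]} mm")
print(f"in-mask voxels: {phantom.ts.n_voxels}, frames: {phantom.ts.n_frames} "
      f"(TR {phantom.ts.tr} s)")
print(f"planted networks: {phantom.truth.network_maps.shape[0]}")
print(f"planted motion-spike frames: {phantom.truth.spike_frames.tolist()}")
print(f"frames with FD > 0.05 mm:    {np.flatnonzero(fd > 0.05).tolist()}")
# the two lists above agree: each spike is a step displacement whose
# framewise displacement exceeds the 0.05 mm censoring preset exactly once
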