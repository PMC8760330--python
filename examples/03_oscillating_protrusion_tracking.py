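"""Track the oscillating vertical force of a single protrusion over time.

A podosome-like dot oscillating between 40 and 80 pN (period 60 s) is
rendered at 5 s intervals with the default 2 nm sensor noise; the
per-frame indentation force is recovered through the full bandpass ->
stress-inversion -> thresholded-integration chain.
"""

import numpy as np

from forcekit import ProtrusionSource, SubstrateModel, SyntheticCell, SyntheticScene
from forcekit.workflows import dot_force_series

n_frames = 24
prot = ProtrusionSource.sinusoidal(
    n_frames, frame_interval_s=5.0, peak_pn=80.0, trough_pn=40.0, period_s=60.0
)
cell = SyntheticCell(
    trajectory_um=np.tile([24.0, 24.0], (n_frames, 1)),
    body_radius_um=12.0,
    protrusions=[prot],
    central_indentation_amplitude_nm=120.0,
)
scene = SyntheticScene((48.0, 48.0), 5.0, n_frames, [cell], noise_sd_nm=2.0, rng_seed=1)
substrate = SubstrateModel(pixel_size_um=0.5)

recovered = dot_force_series(scene, substrate)
truth = prot.force_series_pn

print(" t(s)  true(pN)  recovered(pN)")
for f in range(n_frames):
    print(f"{5*f:5d}  {truth[f]:8.1f}  {recovered[f]:13.1f}")
err = np.abs(recovered - truth).max()
print(f"\nmax |error| {err:.1f} pN ({100*err/80:.1f}% of the 80 pN peak); "
      f"recovered max {recovered.max():.1f} pN")
print("The 4 Pa threshold estimator tracks the oscillation to within a few pN.")
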