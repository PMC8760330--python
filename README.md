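# forcekit

Analysis toolkit for **reference-free vertical cell-force microscopy** on
soft elastic micro-cavity sensors, plus the ancillary assays that usually
accompany a cell-mechanics study: single-cell migration tracking, primary
cilium morphometry, scratch-assay closure and ΔΔCt relative gene
expression.

The pipeline starts from 2-D maps of vertical substrate displacement
(nanometre scale, indentation positive) recorded on an elastic layer of
effective stiffness ~6 kPa, and quantifies cellular force exertion at two
scales:

* **whole-cell contractility** — the *indented volume*
  `V = A · ū` (retained area × mean indentation) under each cell mask,
  after excluding pixels indented less than 20 nm;
* **sub-cellular force transmission** in spatially Fourier-filtered maps
  (raised-cosine bandpass, 0.1–0.6 µm⁻¹):
  * *twist dipoles* — paired push–pull lobes where a focal adhesion
    transmits horizontal contractile force; twist amplitude converts
    linearly to force at **6.6 nm per nN**;
  * *protrusion dots* — ~2 µm confined indentation cores surrounded by a
    ring of upward pulling (the podosome-like signature); the vertical
    force is `F = A · s̄` over the connected stress patch at or above a
    4 Pa threshold, where the stress map `s = (E_eff/t) · G⁻¹ ∗ u` is the
    Tikhonov-regularised deconvolution of the Winkler + Gaussian-coupling
    substrate response.

A forward simulator (`forcekit.synthetic`) renders displacement scenes of
migrating contractile cells with known ground truth — broad cell-body
indentation, focal-adhesion dipoles, oscillating pN-scale protrusions and
Gaussian sensor noise — so every estimator in the package is validated by
round-trip recovery.

## Worked example

```python
import numpy as np
from forcekit import (SubstrateModel, ProtrusionSource, SyntheticCell,
                      SyntheticScene)
from forcekit.workflows import dot_force_series

prot = ProtrusionSource.sinusoidal(24, frame_interval_s=5.0,
                                   peak_pn=80.0, trough_pn=40.0, period_s=60.0)
cell = SyntheticCell(trajectory_um=np.tile([24.0, 24.0], (24, 1)),
                     body_radius_um=12.0, protrusions=[prot],
                     central_indentation_amplitude_nm=120.0)
scene = SyntheticScene((48.0, 48.0), 5.0, 24, [cell],
                       noise_sd_nm=2.0, rng_seed=1)
substrate = SubstrateModel(pixel_size_um=0.5)   # 6 kPa, 10 µm layer

recovered = dot_force_series(scene, substrate)  # pN per frame
print(recovered.round(1))
```

prints (seed 1)

```
[58.1 69.9 73.3 78.1 75.6 68.2 58.8 48.7 39.3 37.7 39.8 46.1 58.6 69.5
 76.  79.5 76.  70.5 60.2 46.  40.3 40.7 39.8 48.6]
```

— the per-frame vertical force of a podosome-like protrusion oscillating
between 40 and 80 pN, recovered through the full
bandpass → stress-inversion → thresholded-integration chain to within a
few pN of the injected ground truth despite 2 nm sensor noise.

More narrative examples live in `examples/` (one script per capability:
simulation + indented volume, feature detection, oscillation tracking,
migration metrics, morphometry/expression/statistics).

A thin CLI mirrors the library for batch work on TIFF stacks:

```bash
forcekit simulate --config scene.yaml --out data/ --seed 1
forcekit filter --low 0.1 --high 0.6 data/displacement.tif filtered.tif
forcekit volume --masks data/masks.tif --threshold-nm 20 data/displacement.tif
forcekit features --stress-threshold-pa 4 filtered.tif
forcekit track --masks data/masks.tif --stack data/displacement.tif
forcekit cilia traced.csv   |  forcekit qpcr ct.csv  |  forcekit scratch widths.csv
```

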