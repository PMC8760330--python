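# Methods

This note documents the models, estimators and numerical choices behind
forcekit, in the spirit of a methods supplement: what each computation
assumes, which parameters matter, and what the synthetic-data validation
does and does not show about real recordings.

## Substrate model

The sensor is modelled as a **Winkler foundation with lateral Gaussian
coupling**: a vertical stress field `s(x)` produces the displacement

```
u(x) = (t / E_eff) · (G_σ ∗ s)(x)
```

where `E_eff` is the effective stiffness of the layer stack (default
6 kPa — the soft-tissue regime the sensors operate in), `t` the elastomer
thickness (default 10 µm) and `G_σ` a unit-mass Gaussian of width
`σ = 0.5 µm` describing how a local load deforms neighbouring material.
At the defaults the Winkler coefficient is `E_eff/t = 0.6 Pa/nm`, so a
100 nm indentation corresponds to 60 Pa of local stress — the right order
for adherent epithelial cells.

This is a deliberate simplification: the original instrument class
converts displacement to stress with a finite-element model of the full
layered cavity. forcekit's inverse is defined against its *own* forward
model, so forward → inverse consistency is exact by construction and is
what the recovery tests certify. The coupling width doubles as the
sensor's lateral resolution; 0.5 µm keeps the deconvolution gain at the
0.6 µm⁻¹ analysis band edge below ~10, which is what makes stress maps
usable at the default noise level (see *Regularisation*).

All units are fixed package-wide: displacement nm (indentation
**positive**), lateral distances µm, stress Pa, vertical force pN
(1 Pa·µm² = 1 pN), horizontal force nN, time s.

## Bandpass filtering

Sub-cellular analysis operates on maps filtered with a raised-cosine
annulus in spatial frequency. Defaults: passband **0.1–0.6 µm⁻¹**,
rolloff 0.03 µm⁻¹, mirror-padding to the next power of two before the
FFT (suppresses wrap-around), DC removed exactly whenever the low cut is
positive.

Two parameters required actual care:

* **Low cut 0.1 µm⁻¹** — the broad cell-body indentation (Gaussian scale
  ~7–14 µm) must be removed essentially completely: its residual is
  additive under every force feature. 
* **Rolloff 0.03 µm⁻¹ on the low side** — with a taper reaching down to
  0.05 µm⁻¹, roughly 0.5% of the body's mass leaks through, which is
  ~2 nm in real space: the same magnitude as the upward-pulling rings of
  protrusion dots. Narrowing the taper to [0.07, 0.1] µm⁻¹ cuts the
  residual below 0.4 nm while *improving* dipole amplitude transfer
  (97% of the rendered twist amplitude survives filtering).

## Indented volume

Per cell and frame: pixels inside the mask with indentation strictly
below the threshold (default 20 nm) are excluded; the volume is the sum
of pixel area × indentation over the survivors (equivalently retained
area × mean retained indentation). Pixels exactly at the threshold are
retained; missing (NaN) pixels never count. The estimator is exact by
construction (it is a finite sum) and is tested against an independent
per-pixel loop at 1e-9 relative.

## Stress inversion and regularisation

`displacement_to_stress` inverts the forward model in Fourier space:

```
ŝ = (E_eff/t) · û · G / (G² + λ)
```

with Tikhonov parameter λ (default **0.03**). The default suits the
package's default sensor noise of 2 nm per pixel: the peak noise
amplification of the Tikhonov kernel is `1/(2√λ) ≈ 2.9`, which keeps the
per-pixel stress noise near 1 Pa — well below the 4 Pa feature
threshold. For noiseless synthetic data a tiny λ (e.g. 1e-9) makes the
inversion essentially exact. Requesting λ ≤ 0 warns and substitutes a
minimal regulariser.

Because the Tikhonov kernel cuts off abruptly at the frequency where
`G² = λ`, compact stress features would ring; a raised-cosine
**apodizer** anchored at that same band edge converts the truncation
into a small mass-preserving blur (and halves the peak noise gain). This
matters for integrated-force accuracy: without it, disk-integrated
forces oscillated by ±2% with integration radius even on noiseless data.

## Force features

**Twist dipoles.** Local maxima and minima above 5 nm (after filtering)
are paired greedily by amplitude within a 4 µm pairing radius; the twist
amplitude is half the peak-to-trough difference, with sub-pixel
refinement by a separable log-quadratic fit (exact for Gaussian lobes).
Force = amplitude / 6.6 nm·nN⁻¹, the calibration the simulator embeds
identically. Pairs whose lobe depths differ by more than 3× are
rejected: genuine dipoles are balanced, whereas a protrusion core
flanked by its much shallower pulling ring is not — without this gate,
strong dots occasionally register as twists under noise.

**Protrusion dots.** Connected indentation components above 5 nm are
candidate cores. Their diameter is measured on the **half-depth (FWHM)
contour** so that it reflects geometry rather than the instantaneous
force (the 5 nm contour of an 80 pN dot is twice as wide as that of a
40 pN dot); the default acceptance range is 1–4 µm. Two morphological
gates separate dots from dipole lobes:

* *twin-lobe rejection* — no opposite extremum deeper than half the core
  peak within 3.5 µm;
* *ring check* — the annulus from 2 footprint-radii outward (3.5 µm deep)
  must show net upward displacement, relative to the local background
  median, in at least half of 8 angular sectors. Judging against the
  local background rather than absolute zero makes the test robust to
  any residual broad deformation; anchoring the annulus on the full
  footprint (not the FWHM core) keeps the dot's own positive skirt out
  of the ring zone.

**Indentation force.** Following the area × mean-stress convention, the
force of a dot is integrated over the connected patch of stress ≥ 4 Pa
containing the stress peak, inside the (slightly dilated) core mask.
Using the connected patch rather than all supra-threshold pixels in the
mask removes a +5–10 pN bias from rectified noise pixels. The threshold
itself biases the estimate down by roughly `4 Pa × core area` (~2–4 pN
at the defaults); validation therefore reports per-frame errors relative
to the oscillation peak. On noiseless scenes, thresholdless integration
over the dilated core recovers injected forces to ±0.3%; under default
noise a 40–80 pN oscillation is tracked with worst-case per-frame errors
of 7–8 pN (<10% of the 80 pN peak) across seeds.

**Linking and classification.** Features are linked frame-to-frame by
greedy nearest-neighbour assignment under a 2 µm gate (configurable gap
tolerance); a cell counts as protrusion-bearing when at least one dot
track persists ≥ 3 frames.

## Migration

Masks are linked by nearest centroid (greedy, deterministic, 10 µm step
gate). **Speed** is path length / elapsed time (the manual-tracking
convention), **straightness** is net displacement / path length (NaN for
a zero-length path, rather than 0). Contact = 8-connected adjacency of
distinct labels; the inclusion rule keeps cells with a contiguous
contact-free window (default ≥ 2 h, configurable because different
stages of such studies use 2 h and 4 h windows) and computes all
summaries on that window. A run of k free frames spans (k−1) intervals.
The speed–force coupling is the Pearson correlation of first differences
of the speed and indented-volume series — first differences, not
smoothed derivatives; an optional moving average can be applied upstream
by the caller.

## Morphometry and expression

Cilium length is the polyline arc length (rigid-motion invariant;
skeleton tracing is upstream of this package). Ciliation fractions are
reported as computed from the counts — note that published count pairs
do not always reproduce their printed percentages, which the report
builder flags rather than hides. ΔΔCt uses replicate-paired
`ΔCt = Ct_target − Ct_reference`, `fold = 2^(−ΔΔCt)` against the
calibrator condition, and the interval
`[2^−(ΔΔCt+sd), 2^−(ΔΔCt−sd)]` with sd the replicate standard deviation
of ΔCt. Scratch closure is width-based: `100·(w₀ − w_end)/w₀`.

## Statistics

Group summaries are mean ± SEM (sample sd, n−1). The two-sample test is
the pooled-variance Student's t-test (two-sided), implemented from the
closed form with the p-value from the t distribution; Welch's variant is
available by flag since real group variances often differ. Degenerate
zero-variance groups with equal means return t = 0, p = 1. The test's
type-I error is verified empirically (5000 null simulations, α = 0.05 ±
0.015) and its power against the noncentral-t closed form.

## Synthetic scenes: what they emulate, and what they do not

The generator reproduces the statistical structure the analyses assume:

* **cell body**: Gaussian indentation, amplitude default 160 nm with
  σ = 0.55 × body radius (25 µm default, ~1960 µm² area). Via the closed
  form `V = 2πσ²(A − θ)` this yields ≈165 µm³ indented volume at the
  20 nm threshold — the scale reported for control epithelial cells; the
  simulated knockout condition injects 1.6× that amplitude.
* **focal adhesions**: two opposite Gaussian displacement lobes
  (σ 0.8 µm, separation 3 µm) scaled to 6.6 nm of twist per nN; default
  forces 2–6 nN.
* **protrusions**: a volume-conserving stress pattern — a cosine-tapered
  disk core (radius 0.6 µm, taper 0.6 µm; observed displacement core
  ~2 µm across after coupling) balanced by a Gaussian-profile ring at
  3.5 µm — with sinusoidal force series between 40 and 80 pN (period
  120 s by default; oscillation extremes follow the reported pN range).
  The taper keeps the core's spectrum inside the band the inversion can
  restore. 
* **kinematics**: persistent random walk (fixed step = speed × interval,
  Gaussian heading diffusion, reflecting margins), default 0.32 µm/min at
  5-min frames over migration scenes, 5 s frames for fine structure.
* **noise**: i.i.d. Gaussian, 2 nm sd per pixel.

All randomness flows through explicit integer seeds
(`numpy.random.default_rng([seed, frame])`); identical seeds give
bit-identical frames, and rendering is linear in the sources.

Not emulated: substrate viscoelasticity and drift, spatially correlated
sensor noise, cell divisions and shape changes, lateral displacement
components, and any coupling between migration speed and contractility.
Passing recovery tests therefore certify the *estimators* under the
stated model, not the instrument chain or segmentation quality on real
recordings.

## Problem sizes used in validation

Recovery and end-to-end tests run on deliberately small scenes chosen to
exercise every code path at full fidelity: 48 µm fields at 0.5 µm pixels
(fine structure, 10–24 frames at 5 s) and 150 µm fields at 1 µm pixels
(migration, 26 frames at 5 min ≈ a 2 h window); the two-population
comparison uses 12 cells per line for contractility and three
experiments per line (sizes 5/3/4 and 5/6/9) for the protrusion-bearing
fraction, mirroring a realistic experimental design.

## Known limitations

* The displacement-to-stress step is self-consistent with the package's
  forward model but is not a finite-element solution of a real layered
  cavity; absolute stress values on real data inherit the Winkler
  approximation.
* The 4 Pa-threshold force estimator has a small force-independent
  downward bias and loses meaning for features whose peak stress
  approaches the threshold.
* Dot/twist disambiguation is morphological; the original workflow gated
  features on co-localised immunostaining, which is out of scope here.
* The twist amplitude metric (half peak-to-trough of the paired lobes)
  is an operational definition; whether the original calibration used
  lobe distance, rotation angle or amplitude is not recoverable from the
  available description, so the same definition is embedded in simulator
  and analyser to keep the 6.6 nm/nN constant self-consistent.
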