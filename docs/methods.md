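# Methods

This note documents the model, the numerical choices, the synthetic-data
conditions and the known limits of the package.  Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Forward model

The conduction problem ∇·(σ∇u) = 0 is solved on a 2D cross-section of the
nerve-in-cuff geometry with linear triangular finite elements.  Two
reductions relative to the physical 3D problem are made deliberately:

1. **Dimensionality.** The localization task is cross-sectional, so the
   cylinder is collapsed to its cross-section.  The out-of-plane extent
   enters as a slab thickness t = 1 mm (the electrode pad length): bulk
   conductance scales with t while the lumped contact impedance does not,
   and this single constant sets the absolute voltage scale.  With it, the
   model produces tens-of-mV carrier voltages and few-µV evoked δV — the
   scales at which the µV-denominated processing thresholds (3 µV noise
   exclusion) and the ~200 µV CAP contaminant are meaningful.
2. **External medium.** Current that physically leaks axially at the cuff
   edges is represented by a thin conductive annulus (1.5 S/m, saline-like)
   between the nerve surface and the electrode ring.  Its default outer
   radius is 0.75 mm, i.e. a 50 µm film: a wide bath would carry almost
   all of the drive current around the nerve azimuthally, which a snug
   cuff prevents; the film reproduces the partial-leakage situation while
   keeping the mesh boundary a single circle carrying the pads.  The
   radius is a parameter of `build_mesh` for anyone wanting a wide-bath
   geometry.

Electrodes follow the complete electrode model.  The paper-style contact
impedance of 1 kΩ is interpreted as a lumped per-electrode value; it is
converted to the CEM surface parameter via the pad area (arc × thickness),
making the per-electrode contact conductance 1/(1 kΩ) independent of the
slab thickness.  A `contact_model="surface"` option accepts Ω·m² directly.
Terminal voltages are gauged to mean(U) = 0 over the ring, standing in for
the cuff's ring reference electrode; the gauge is enforced with a Lagrange
multiplier, keeping the system symmetric so that reciprocity holds to
factorization precision (verified to ~10⁻¹³ relative; the acceptance bound
is 0.1%).

The mesh is built from concentric node rings (Delaunay-triangulated):
spacing h inside the nerve, up to 3h mid-annulus, h/2 at the
electrode-bearing boundary.  The pipeline default is h = 30 µm
(≈4600 elements); at this resolution halving h changes boundary voltages
by <1%.  The sub-2000-element h = 60 µm mesh is used where a brute-force
finite-difference Jacobian oracle must stay cheap.

**Jacobian.** Sensitivities are computed by the adjoint method:
∂V/∂σₑ = −t·areaₑ·(∇u_drive·∇w_meas), with the measurement field solved
for unit mean-free current patterns.  Element columns are projected onto
the 40 µm voxel grid by splitting each element's (already area-integrated)
sensitivity over the voxels it overlaps, with overlap weights estimated by
a 16-point barycentric supersample; sample points falling in voxels whose
centers lie outside the nerve disk snap to the nearest retained voxel, so
the total nerve-region sensitivity is conserved exactly.  Summing (rather
than averaging) element entries is what makes δV = J_vox·δσ_vox hold for a
voxel-uniform perturbation.

## Synthetic data: what it emulates

The generator reproduces the study conditions of a fascicle-stimulation
experiment:

* **Anatomy.** 1.4 mm nerve; three elliptical fascicles (tibial largest,
  then peroneal, then sural) at distinct angular sectors.  Nerve-to-nerve
  variability is uniform jitter of ±24° in angle and ±70 µm in radial
  position (plus ±10% size and free orientation), chosen to reproduce
  cluster scatter of roughly 4–6% of nerve diameter, the variability scale
  reported for real nerves; draws violating containment or pairwise
  separation are rejected and resampled.  Left-side nerves are mirrored
  anatomy.
* **Activity.** One fascicle's conductivity rises by a fraction
  (default 5×10⁻⁴, i.e. 0.05%) with a raised-cosine time course
  parameterized by its width at 30% of peak (default 0.7 ms) and an onset
  latency (default 0.7 ms).
* **Recording.** Each channel is A(t)·cos(2πf_c t) + CAP(t) + white noise,
  with A(t) stepping from the baseline to the perturbed-field forward
  voltage along the activity profile.  The CAP contaminant is a biphasic
  Gaussian-derivative template (σ = 0.25 ms, ~200 µV peak, per-channel
  gain jitter ±30%) whose spectrum lies far below the 4–8 kHz carrier
  band.  Stimulation runs at 5 Hz; the full protocol is 300 trials over
  60 s per injection, 14 injections (14 min per branch).
* **References.** MicroCT-like (4 µm px) and histology-like (2 µm px)
  sections are rendered after per-axis shrinkage (defaults around
  0.88–0.92, motivated by ~10% fixation shrinkage) and a random rotation,
  with a bright fiducial dot at the distorted cuff-opening position; in
  histology the sural fascicle is rendered without tracer labelling and
  must be identified downstream as the largest unlabelled mask.  Ground
  truth (pre- and post-distortion centers, masks, transform) is always
  serialized alongside.

**Noise targeting.** The channel white-noise SD needed for a requested
*averaged-trace* SNR follows from the narrowband noise picture: after the
±2 kHz demodulation band, envelope noise SD ≈ σ·√(4·bw/fs), divided by √N
for N averaged trials, so σ = (peak δV/SNR)·√N·√(fs/(4·bw)).  The empirical
averaged-trace SNR then lands near the request (the Butterworth band edge
makes it a few percent conservative), which is asserted in the tests.

**What the generator does not emulate:** stimulus artifacts, electrode
drift and DC offsets, correlated (non-white) noise, biophysical CAP
dispersion along the nerve, frequency-dependent tissue impedance, and any
3D current spreading beyond the slab reduction.  Passing tests therefore
show the *pipeline* is correct and calibrated under these conditions, not
that real recordings of this quality are guaranteed.

## Signal chain

Demodulation computes the analytic-signal magnitude in the carrier band by
quadrature mixing: x(t)·e^(−i2πf_c t), 4th-order Butterworth low-pass at
the 2 kHz bandwidth, applied forward-backward (zero phase), magnitude × 2.
This is mathematically the band-pass + Hilbert-magnitude demodulator, but
computed locally in time: a global FFT Hilbert transform spreads filter
edge transients across the record at the ~3×10⁻⁵ relative level, which
would mask modulations of order 10⁻⁴.

Epochs of (−10, 40) ms around each trigger are averaged (the first and
last trials are dropped to avoid filter settling); the (−8, −1) ms
baseline mean is subtracted, and the background noise SD is the temporal
SD of the trial-averaged (100, 180) ms inter-stimulus segment.  QC drops
traces with noise SD > 3 µV, traces touching a faulty electrode (drive or
measurement) and saturated channels.  Response metrics: peak |δV| in the
0–5 ms window; onset is the last upward crossing of 3× the noise SD before
the peak (the threshold is configurable — onset has no universal
definition); duration is the contiguous time above 30% of peak, with
linear interpolation at the crossings; conduction velocity is stimulation
distance / onset.

## Reconstruction

The measurement vector is each retained trace's signed value at the time
of the peak mean |δV| (envelope changes are converted to signed voltage
changes with the sign of the baseline carrier voltage).  The Tikhonov
factor uses the SVD of the row-reduced voxel Jacobian; the fixed-α rule
λ = 10⁻²·s₁² is the deterministic default and generalized cross-validation
is available as an option.  Noise epochs for the voxel correction are
drawn per trace from its measured background noise level (30 epochs by
default; at least 20 required).  The z-score step matters beyond
significance scaling: it flattens the ring geometry's radially varying
sensitivity, which otherwise biases reconstructions toward the boundary.

Post-processing operates on the positive (conductivity-increase) lobe of
the z-score image: median filter of Chebyshev radius 1, mean filter of
radius 3, reflection padding at the array edge with outside-mask voxels
held at zero, then min–max normalization inside the mask.  The CoM is the
intensity-weighted centroid over voxels ≥ 0.5 × max.  All angular outputs
use one convention: degrees clockwise from the fiducial (cuff opening) at
12 o'clock.

## Co-registration and statistics

Reference sections are registered by fitting an ellipse to the nerve
outline (algebraic least squares), rescaling along its axes onto the
700 µm circle, rotating the detected fiducial to 0°, and flipping
left-side nerves horizontally; a manual rotation override exists because
automated fiducial detection may not match a human operator's choice.  A
circle-fit residual above 8% of the nerve radius after rescaling raises a
co-registration failure.

The two-way ANOVA (fascicle × technique) uses the standard balanced
sum-of-squares decomposition with the interaction term when replicates
allow; main effects are the headline.  Angles are treated as linear after
rotating the frame so the cut falls in the widest empty gap of the pooled
angles; a guard raises if any cluster still spans ≥180°.  The scatter
metric is the per-cluster SD of x and y about the cluster mean, averaged
over axes and then over fascicles, one value per technique (µm and % of
nerve diameter).

## Problem sizes and determinism

Simulated sessions in the tests and the acceptance script use 20–25 trials
per injection at 25 kHz sampling with noise retargeted to averaged-trace
SNR ≈ 17 — the quantity that governs reconstruction quality — rather than
the full 300-trial, 60 s protocol, whose arithmetic is checked separately.
The headline benchmark runs 20 phantoms through the complete raw-signal
chain; the repeated statistics study uses trace-level noise injection
(δV + noise at the averaged-trace scale), whose equivalence to the raw
chain is asserted by the envelope-consistency and 1/√N averaging tests.
Every stochastic stage takes an explicit seed; identical seeds give
bit-identical recordings, images and reports.

## Known limitations

* The 2D slab is a caricature of 3D current spreading; absolute δV/V
  (~1–2×10⁻⁴ here) sits below the ~4×10⁻⁴ fractional changes measured in
  vivo, and no slice-selection step exists because there is only one slice.
* The inversion uses the same forward model that generated the data (an
  "inverse crime"); the localization numbers quantify pipeline and noise
  behavior, not model-mismatch robustness.
* 0th-order Tikhonov with a fixed α is deliberately plain; no attempt is
  made at iterative or nonlinear reconstruction.
* The CAP contaminant is a fixed template; real CAP shape varies with
  fiber population and distance, and stimulus artifacts are absent.
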