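# neureit — fast neural EIT of peripheral nerve, on the desk

`neureit` is a desk-scale simulator and reconstruction pipeline for **fast
neural electrical impedance tomography (EIT)** of a peripheral nerve.  Fast
neural EIT images the transient (~1 ms) impedance decrease of depolarizing
neural tissue: a cuff of electrodes around the nerve drives a sub-threshold
6 kHz, 60 µA carrier between pad pairs while the evoked compound action
potential (CAP) travels past; the stimulus-locked amplitude modulation of
the carrier, averaged over hundreds of trials, is inverted into a
cross-sectional image of the conductivity change, localizing the active
fascicle (tibial, peroneal or sural in the rat sciatic nerve model).

The package is aimed at people developing or teaching EIT reconstruction
and validation methodology who want the whole measurement chain —
electrode model, raw signals, demodulation, inversion, co-registration,
statistics — as transparent, testable Python, with ground truth always
attached.

## The model in brief

* **Forward model.** The nerve cross-section (radius 0.7 mm, baseline
  conductivity σ = 0.3 S/m) sits in a thin, more conductive film
  (1.5 S/m) that carries the current leaking at the cuff edges.  Fourteen
  pads (0.14 mm ≙ 11.5° arc, 25.7° apart) are modelled with the complete
  electrode model (CEM) with 1 kΩ lumped contact impedance, discretized
  with P1 finite elements on a graded triangle mesh.
* **Measurement.** The 4-off drive pattern: injection *i* drives the pair
  (*i*, *i*+4 mod 14); all 14 electrodes are recorded for each of the 14
  injections → 196 transfer impedances per dataset.
* **Sensitivity.** The linearization δV = J·δσ, with J computed by the
  adjoint method, J₍d,m₎,ₑ = −t·areaₑ·∇u_d·∇w_m, and projected onto a
  40 µm voxel grid (~960 voxels inside the nerve mask).
* **Inversion.** 0th-order Tikhonov, δσ = argmin ‖Jδσ − δV‖² + λ‖δσ‖²
  with λ = α·s₁(J)², followed by noise-based voxel correction: each voxel
  is divided by the SD of reconstructions of background inter-stimulus
  noise epochs, giving a z-score image.  Post-processing is a median
  filter (radius 1), mean filter (radius 3) and min–max normalization;
  the fascicle center of mass (CoM) is the intensity-weighted centroid of
  the voxels above half maximum (FWHM rule).
* **Validation.** Reference "microCT" and "histology" cross-sections are
  rendered from the same phantom with tissue-shrinkage distortion, then
  co-registered back (ellipse fit → per-axis rescale → fiducial rotation →
  left-nerve flip); fascicle separation and technique agreement are tested
  with a balanced two-way ANOVA on the angular CoM position, plus a
  per-technique scatter metric.

## Worked example

`examples/02_simulate_and_reconstruct.py` draws a phantom, synthesizes a
noisy recording session (20 trials per injection at 25 kHz, noise sized
for averaged-trace SNR ≈ 17) and runs the full reconstruction:

```
traces: 196 total, 196 retained after QC
peak averaged δV at t = 1.24 ms, best-channel SNR 18.4
true tibial center:      (  174.2,  -280.5) µm
reconstructed CoM:       (  140.8,  -198.9) µm (R = 244 µm, θ = 145°)
localization error: 88.2 µm = 6.3% of nerve diameter
strongest trace: peak 6.56 µV, onset 0.79 ms, duration above 30% of peak
0.77 ms, conduction velocity 19 m/s, SNR 18.4 (25.3 dB)
```

The peak lands where the activity profile peaks (0.7 ms onset + half the
pulse), the δV is a few µV riding on a tens-of-mV carrier (a ~10⁻⁴
relative modulation), and the CoM error is well under the fascicle size.
The other examples cover the forward model and reciprocity (`01`),
co-registration round-trips (`03`) and the five-nerve statistical study
(`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
neureit simulate --seed 3 --fascicle sural --out runs/sim
neureit reconstruct runs/sim/recording.h5 --out runs/recon
neureit coregister runs/sim/references --out runs/coreg
neureit run-all --seed 1 --out runs/study
```

## Layout

```
src/neureit/
  mesh.py        graded triangle mesh + Gmsh-style text I/O
  forward.py     CEM solver, protocol, adjoint Jacobian, voxel projection
  phantom.py     fascicle phantoms, activity events, raw recordings,
                 reference-image rendering
  signal.py      demodulation, epoch averaging, QC, CAP metrics, t-test
  recon.py       Tikhonov inversion, z-scoring, filtering, FWHM CoM
  coregister.py  circle/ellipse fits, frame registration, CoM comparison
  validate.py    two-way ANOVA, scatter metric, report generation
  pipeline.py    end-to-end orchestration (shared by examples, CLI, tests)
  cli.py         thin argparse front end
```
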