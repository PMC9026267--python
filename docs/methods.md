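# Methods

## Scope and model

`sixpacktomo` implements both halves of a double six-pack holographic
tomography experiment in software: a forward simulator that turns a 3D
refractive-index phantom into the two multiplexed off-axis holograms the
two cameras would record, and the reconstruction pipeline that turns
such a frame pair (plus a background pair) back into a 3D RI tomogram.
Because the forward and inverse halves share one weak-scattering model,
ground-truth comparisons isolate the properties of the *reconstruction*
(carrier layout, channel separation, Ewald coverage, missing-cone
constraints) rather than residual physics mismatch.

### Illumination and optics

Twelve plane waves at a polar angle of up to 39° in air (refracted into
the medium by Snell's law) illuminate the sample simultaneously;
channels 1–6 and 7–12 form two orthogonal polarization groups routed to
cameras 1 and 2. Polarization is modeled as ideal binary routing — no
Jones calculus, no birefringent samples. Default azimuths interleave
the two groups every 30° for uniform coverage. The optical constants
default to the reference hardware: λ = 632.8 nm, 106× magnification,
8-bit camera with 5.2 µm pixels (sample-plane pitch 49 nm).

The **detection NA defaults to 1.0** in simulation. Six CC lobes of
radius NA/λ, a DC lobe of radius 2NA/λ, and six conjugate lobes must all
fit without overlap inside the camera Nyquist disc (10.2 cycles/µm at
49 nm pitch); at NA 1.35 the admissible carrier annulus is too thin to
hold six carriers in a half-plane with full conjugate clearance, while
NA 1.0 admits the default layout with margin. The analytic spot-size
and throughput calculators take the physical NA 1.35 and reproduce the
469 nm spot, 66.7 µs minimum exposure, and ≈7 mm/s maximum flow speed.

### Carrier layout and coherence gating

The default layout places the six carriers at azimuths 15°–165° in 30°
steps (all conjugates in the opposite half-plane) on the radius that
bisects the admissible annulus, snapped to integer FFT bins so
demodulation is leak-free. `validate_carrier_layout` enforces
|c| ≥ 3k_NA, |c| + k_NA ≤ Nyquist, and |cᵢ ± cⱼ| ≥ 2k_NA; every entry
point validates before use.

Coherence gating uses a Gaussian degree of coherence
γ(Δ) = exp(−πΔ²/(2l_c²)) with l_c = 42.4 µm; the 1.16 mm echelon step
makes |γ| underflow to zero, so only matched sample/reference pairs
interfere. The synthesized intensity contains the sample and reference
autocorrelations and all γ-weighted sample×reference cross terms;
sample–sample and reference–reference interference is omitted (the same
delays annihilate it). Setting the echelon step to zero re-enables the
mismatched terms and is used as a negative control. Frames are scaled
to ~70% of full well and quantized to the camera bit depth; optional
Poisson shot noise is seeded.

### Forward propagation

The default `rytov_projection` model takes the complex log of the
transmitted field as i·(2π/λ)·∫(n − n_m) dl along the refracted
illumination ray, referenced to the axial center plane, then applies the
detection pupil (per-channel low-pass at NA/λ) to the complex envelope.
This is the exact adjoint of the Ewald-cap inversion at low spatial
frequency, which is what makes round-trip accuracy a meaningful test.
A `multislice` angular-spectrum propagator (phase screens with obliquity
correction, refocused to the center plane) is provided as a
higher-fidelity cross-check; the two agree to ~2% in through-center
phase for weak contrast.

### Reconstruction

Camera-2 frames are flipped horizontally (with optional integer-pixel
cross-correlation alignment) to undo the second camera's mirror. Each
hologram is FFT'd; each CC lobe is cropped as a disk of radius ≤ NA/λ,
rolled to baseband, zero-padded back to the frame, and inverse
transformed. Wavefronts are divided by their background counterparts,
log-amplitude and phase are extracted, the phase is unwrapped with 2D
reliability-sorting unwrapping (scikit-image), a complex global offset
is removed via the median over the frame border, and a 3×3 median
filter suppresses impulsive noise (both defaults config-exposed; the
unwrapping algorithm is recorded in metadata).

Each field's 2D spectrum is deposited on its Ewald cap
(k_z = √(k_m² − k_x² − k_y²), K = k − k_i, prefactor −2i·k_z from the
Fourier diffraction theorem under Rytov) by nearest-voxel assignment
with sum/count averaging — trivially idempotent, matching the
"averaged where they overlapped" rule; evanescent components are
dropped. Conjugate samples are co-deposited so the spectrum is
Hermitian and the potential real. The 3D grid inherits the 2D frequency
step (128³ over the 12.6 µm field of view → 98 nm voxels).

**RI conversion.** The scattering potential convention is
f = (2π/λ)²(n² − n_m²). The transcribed inversion formula
n = n_m·√(1 + fλ²/4π²n_m²) is quadratic in contrast, while the forward
phase is linear in (n − n_m); at bead contrast (Δn = 0.113) the mismatch
alone would cap contrast recovery at ~96%. The package therefore treats
the forward/inverse round trip as the binding contract and defaults to
the matching linearization n = n_m + fλ²/(8π²n_m); the quadratic form
is available via `conversion="quadratic"` (differences < 5×10⁻³ in n on
the bead study). The choice is recorded in tomogram metadata.

### Constraints and regularization

*Non-negativity*: each iteration clamps n < n_m to n_m, Fourier
transforms, resets every measured-support frequency voxel to its
original value (newly filled missing-cone voxels are kept), and inverse
transforms — the measured data are exactly preserved at the end of every
iteration. Default 100 iterations or relative change < 10⁻⁵. Because
the reset is the last half-step, the fixed point retains a carpet of
residual negatives at the ~10⁻³ level (the measured spectrum itself is
slightly inconsistent with non-negativity); excursions beyond that
scale are strongly removed (typically ~7× fewer voxels below
n_m − 10⁻³), and the worst voxel always improves.

*TV regularization*: monotone FISTA (MFISTA; rejected steps keep the
previous iterate, so the objective sequence never increases) on
½‖Au − b‖² + α·TV_ε(u), isotropic 3D TV smoothed with
ε = 10⁻³ × dynamic range, α defaulting to 10⁻³ × dynamic range, 200
iterations with a stall-based early stop. The blurring operator A is an
anisotropic Gaussian PSF whose widths default to the *measured*
edge-spread resolution of the tomogram being regularized (anchored at
its contrast centroid — adequate for compact objects); an
optics-derived heuristic is the fallback and explicit sigmas override
both. On the bead study TV shifts the in-mask mean RI by ≈0.2%,
consistent with regularization being contrast-preserving.

## Metrics

Accuracy is reported two ways: 100·⟨n⟩/n_true and the stricter
100·(⟨n⟩ − n_m)/(n_true − n_m), over either the full 3D ground-truth
mask or its central z-slice. Resolution is the FWHM of the derivative
of an RI line profile across a bead edge, per axis; this operationalizes
the usual edge-spread procedure (the method tag is recorded so
alternatives can be added). The experimentally reported resolutions are
kept only as annotation constants — simulated values are compared
directionally (double ≤ single), never against those numbers.

## Study conditions and what the tests show

The acceptance study simulates one 3 µm bead (n = 1.457, medium 1.344)
noiselessly on 256² frames at 49 nm pitch, 12 angles at 39°, and
reconstructs on a 128³ grid — sizes chosen so a full run completes in a
few minutes on one core. Under these conditions the full pipeline
recovers 99.4% of the bead RI over the full 3D mask (92.8% relative to
the medium) and overshoots slightly on the central plane (102.6%,
133% relative): with no experimental noise, aberrations, or calibration
error, the non-negativity iteration refills the missing cone
aggressively, and Gibbs overshoot concentrates at the bead center.
Experimental frames additionally suffer camera noise, background drift,
imperfect registration, and polarization cross-talk, none of which the
generator emulates (shot noise is available but off by default) — so
passing these tests demonstrates correctness and internal consistency
of the algorithms, not experimental-grade accuracy on real data.

## Known limitations

- Weak-scattering (Rytov/projection) forward model: no multiple
  scattering; `multislice` is available but still scalar and paraxial
  in its slice stepping.
- No lens aberrations, field curvature, vector diffraction, or partial
  spatial coherence across the field of view.
- Carrier auto-detection from unknown experimental data is not
  implemented; carriers must be declared in the sidecar/config.
- The sperm phantom is a schematic (ellipsoidal head split into
  nucleus/acrosome halves at the 1.40 RI threshold plus a cylindrical
  midpiece); it reproduces threshold structure, not anatomy, and has no
  tail.
- Per-frame volumes only: no time-lapse containers or moving phantoms
  beyond per-frame translation.
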