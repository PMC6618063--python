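# Methods

`flow4d` simulates and processes a retrospectively gated, stack-of-spirals,
four-point phase-contrast (4D flow) MRI examination of a pulsatile flow
phantom, and quantifies the result with the two analysis approaches standard
in cardiac 4D flow work: through-plane volume flow and pathline-based flow
component decomposition. This note records the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Sequence model

The acquisition is a 3D velocity-encoded gradient echo with a stack-of-
spirals trajectory: 2D variable-density spiral interleaves in-plane and
Fourier (phase) encoding through slices. The clinical parameter set is the
default `SequenceParams`: TR 12 ms, TE 3.7 ms, venc 120 cm/s, 10
interleaves per slice partition, readouts limited to 5 ms, 280 mm FOV at a
100×100 matrix (2.8 mm isotropic in-plane), 27% slice oversampling and a
flip angle of 8°. One reference plus three velocity-encoded segments are
played in succession within a heart-phase slot, so the nominal temporal
resolution is `segmentation_factor × 4 × TR` (48 ms for the spiral
protocol; 46.4 ms for the Cartesian reference at TR 5.8 ms and
segmentation factor 2).

### Spiral design

The base interleaf is an Archimedean spiral whose radial pitch follows a
two-zone variable-density profile (fully sampled core out to a configurable
fraction of k_max, default 0.2, then a linear taper to a configurable
undersampling factor, default 1 = uniform). The trajectory is generated by
integrating the arc-length ODE at the 10 µs gradient raster: the traversal
speed |dk/dt| ramps at the slew limit, capped both by the gradient
amplitude (γ̄·G_max) and by the centripetal slew demand (√(γ̄·S_max·ρ) with
ρ the local radius of curvature). Because the continuous speed law is
discretized at the raster, the sampled waveform can exceed the limits by a
few percent; the designer therefore re-checks the discrete waveform and
backs off its safety margin until gradient and slew limits hold sample-wise
(hardware defaults 33 mT/m and 180 T/m/s). Interleaf m is interleaf 0
rotated counter-clockwise by 2πm/10. For the clinical protocol the readout
is ≈3.5 ms, under the 5 ms cap; an `InfeasibleReadoutError` is raised when
k_max is unreachable in the allowed window.

The scan-time model books one k-space line (all four flow segments across
all heart phases) per cardiac cycle per segmentation unit:
`interleaves × round(slices × (1 + oversampling)) / segmentation` RR
intervals, i.e. 460 beats for 36 slices and 510 for 40 at 27% oversampling.
The Cartesian trajectory module only enumerates phase-encode lines (low-high
or linear order); no Cartesian scan-time model is claimed.

## Flow phantom

The phantom is a straight tube along x (radius 9 mm) with a smooth
chamber-shaped bulge in the middle (maximum radius 13 mm over ±60 mm; the
radius profile uses a C∞ bump so all derivatives are continuous). Flow is
axisymmetric and derived from a Stokes stream function
ψ = Q(t)/(2π)·S(ρ/R(x)) with S(η) = 1 − (1 − η²)³, giving a quartic axial
profile u = 3Q/(πR²)(1−η²)² that vanishes with zero slope at the wall and a
radial component that keeps the field *exactly* divergence free for the
varying wall radius. Consequences worth noting:

- The instantaneous flux Q(t) is identical through every cross-section
  (rigid, incompressible). "Stroke volume" in `PhantomSpec` therefore means
  the net volume transported per cycle — what any plane measures — and it
  splits into a systolic ejection lobe (SV − E − A) and two diastolic
  filling lobes (E and A waves). Defaults: 30 ml per cycle (systolic lobe
  15 ml over 320 ms, E wave 10 ml over 250 ms starting at 400 ms, A wave
  5 ml in the final 135 ms ≈ 15% of the 900 ms cycle). The late A wave is
  deliberate: truncating the last 10–20% of the cycle demonstrably loses
  its volume, which is the reason retrospective gating exists.
- Peak fluid speed at the tube throat is 3Q_max/(πr²) ≈ 1.11 m/s, under
  the 120 cm/s venc by construction (validated in `PhantomSpec`).
- Beat-to-beat variability follows the physiological pattern that heart-
  rate variation is predominantly diastolic: for a beat of length RR the
  waveform keeps systole fixed and stretches diastole relative to the mean
  cycle. RR intervals are truncated-normal (900 ± 50 ms by default).

Signal: fluid magnitude 1.0, static-tissue slabs (20 ≤ |y| ≤ 60 mm) 0.6,
background 0. There is no relaxation (T1/T2), fat compartment or intravoxel
dephasing model. Complex image-domain noise is parameterized relative to
the fluid magnitude (default 2%, i.e. SNR 50) and injected in k-space with
the unitary-DFT scaling √N_voxels; for gridded non-Cartesian
reconstruction this scaling is approximate, which is acceptable because no
result depends on the absolute noise calibration.

## Acquisition simulation

The object is the phantom sampled at the voxel centers of the encoded grid
(voxel centers at (i + 0.5)Δ − FOV/2), frozen at each readout's center
time; samples are the exact non-uniform DFT of m(r)·exp(iπ·v_d/venc) at
the trajectory coordinates (the reference segment encodes v = 0), plus
complex white noise. The fast path splits the static (time-invariant) and
fluid contributions and caches per-line in-plane exponentials; it is
algebraically identical to the brute-force NUDFT, which the tests verify.

The sequence free-runs: heart-phase slots live on a continuous absolute
time grid, the k-space line group switches at the first slot boundary at or
after each R wave, and a slot straddling the R wave contributes its
readouts to whichever beat contains them. This matters: if the slot grid
were reset at every R wave the slot phase would be locked to the cardiac
phase, systematically starving the cardiac frames adjacent to the R wave
and biasing the reconstructed flow curve. Free-running slots are also how
a real retrospectively gated sequence behaves.

Respiratory gating: a sinusoidal diaphragm trace is tested once per beat
against a full-width acceptance window — 4 mm for the central 25% of slice
encodes (ranked by |kz|), 7 mm outside. Rejected beats re-queue their line
immediately; the run aborts if acceptance efficiency falls below a floor
(default 5%).

## Retrospective binning

Each accepted readout's time-since-R is mapped onto the average cycle with
the same systole-fixed/diastole-stretched rule (the sorter's systole length
defaults to 40% of the mean RR, configurable in ms — the true split point
of a scanner's sorter is not observable) and hard-binned into
`floor(τ/(RR_mean/n_frames))`, duplicates complex-averaged. With one beat
per k-line and 4×TR = 48 ms slots there are ≈18.75 samples per line per
cycle, so any frame count above ~18 necessarily leaves some (line, frame)
bins empty; empty bins borrow the nearest filled frame of the same line
(cyclic distance), with the borrow count reported. At the default desk
scale (20 frames) the raw fill fraction is ≈0.9. Two-sided linear
interpolation of holes was evaluated and rejected: it smears the sharp
A-wave more than nearest-copy does.

## Reconstruction

Spiral planes are reconstructed by standard convolution gridding: analytic
radial density compensation (annulus area per sample, 2πr·dr/N_il, which
adapts automatically to the variable-density pitch; Voronoi-cell weights
are available as a fallback), Kaiser-Bessel kernel of width 4 on a 1.5×
oversampled grid (Beatty β), inverse FFT, deapodization by the numerically
integrated kernel transform, and cropping. The half-open voxel convention
is implemented as a phase ramp on the samples; the kernel apodization is
evaluated at the unshifted grid positions (the ramp moves the object, not
the kernel envelope). The slice direction uses an exact small inverse DFT
over the kz encodes followed by the slice-oversampling crop. Gridding
matches the directly evaluated density-compensated inverse NUDFT to ≈0.1%
NRMSE on test objects; fully sampled Cartesian data take an exact FFT
route. Velocity maps are v_d = venc·arg(S_d·conj(S_ref))/π with magnitude
|S_ref|; phases beyond ±π are left wrapped (the phantom never wraps).
Geometry-factor normalization is a no-op at SENSE 1 and is not implemented.

## Background correction

Eddy-current offsets appear as a smooth time-invariant background velocity.
Static tissue is detected by low temporal variance of the *speed* (25th
percentile by default, magnitude floor 10% of maximum); one degree-4
polynomial in (x, y, z) — 35 monomials on coordinates normalized to
[−1, 1] — is least-squares fitted per component to the time-averaged
velocity of the masked voxels and subtracted from every frame. Two
subtleties: (i) the fit needs ≥5 distinct slice positions to resolve the
quartic z terms, so very thin volumes cannot be corrected at degree 4;
(ii) speed-SD detection slightly favours voxels where the offset magnitude
is small (the SD of |v + noise| shrinks as |v| → 0), which leaves a
residual ROI mean of a few mm/s after correcting a −0.07 m/s offset under
0.05 m/s noise — comfortably inside the 0.01 m/s reporting precision.

## Flow quantification

A measurement plane is an axis-aligned slice with an in-plane lumen mask
and a unit normal; Q(frame) = Σ_mask (v·n̂)·pixel_area is directly in ml/s
for v in m/s and areas in mm², and the net volume is the rectangle-rule sum
over frames. Peak velocity is the through-plane component maximum (clinical
venc-direction convention), not the speed.

## Pathline analysis

Pathlines are integrated with classical RK4, quadrilinear (x, y, z, t)
interpolation (periodic in the cycle, frame values at bin centers) and a
5 ms step, vectorized over all seeds. Seeds sit at the voxel centers of the
end-diastolic chamber mask (optionally k³ per voxel), each carrying
voxel-volume/k³ of blood. Forward traces run R wave → end systole;
backward traces run R wave → previous end systole through the periodic
cycle. A pathline's first crossing of the end-systolic chamber surface
(trilinear mask interpolation at 0.5) is attributed to the nearest labeled
boundary voxel — inlet, outlet, or wall (everything else). Components:
entered ∧ left = direct flow; entered only = retained inflow; left only =
delayed ejection; neither = residual; any wall crossing discards the
pathline. The bookkeeping closes exactly (components + discarded = seeded
volume), inflow = direct + retained and outflow = direct + delayed by
construction, and on the divergence-free phantom inflow and outflow agree
within a few percent — the sensitive end-to-end quality check this
decomposition is used for in practice.

On reconstructed (noisy, ring-prone) fields a substantial fraction of
near-wall volume (tens of percent at desk scale) is discarded at the wall:
slow particles near the voxelized chamber surface random-walk across it.
This mirrors the real-data behaviour that wall-leaving pathlines are
discarded, but it means component volumes from fully simulated examinations
are systematically smaller than the ground-truth volumes; the conservation
and ensemble-regression checks therefore run on the ground-truth-sampled
field, where discards are ≈0 without noise.

## Evaluation statistics

Ordinary least squares y = βx + α with the F statistic R²(n−2)/(1−R²) on
(1, n−2) degrees of freedom (significance 0.05), and Bland-Altman bias ±
1.96·SD of paired differences (sample SD, n−1). The ensemble consistency
study regresses pathline inflow on outflow across 10 phantoms spanning
8–30 ml transported volume (a wide physiological spread; the upper end is
set by the venc) with a 0.01 m/s velocity perturbation matching the
pipeline's own reconstructed noise level; the wide spread is what gives the
n≈10 regression enough leverage for a stable slope estimate.

## Problem sizes and determinism

The desk-scale protocol used throughout the tests keeps every clinical
sequence parameter but shrinks the matrix to 64²×8 slices (2.8 mm in-plane,
4 mm slices), 20 cardiac frames and ≈100 nominal beats; a full simulated
examination (design → simulate → gate → grid → correct → quantify) runs in
well under a minute on one CPU, and the whole test suite in a few minutes.
All randomness flows from explicit seeds (RR draws, k-space noise,
ensemble perturbations); fixed seeds reproduce bit-identical k-space and
velocity volumes.

## Known limitations

- No off-resonance/chemical shift, concomitant-gradient phase, coil
  sensitivities, SENSE/GRAPPA, or relaxation modeling; the Cartesian
  comparison arm is emulated as fully sampled.
- The phantom is rigid: chamber volume cannot change, so systolic ejection
  and diastolic filling coexist as through-flow rather than alternating as
  in a contracting ventricle, and pathline inflow/outflow reflect the
  diastolic/systolic lobes of the same waveform.
- Frozen-snapshot readouts (no intra-readout motion or flow displacement
  artifacts); the 5 ms readouts make this a small approximation.
- Nearest-frame borrowing caps the effective temporal resolution at the
  48 ms slot spacing regardless of the reconstructed frame count.
- In-vivo quantities (volunteer/patient flows, scanner minutes, in-vivo
  SNR) are outside what a synthetic phantom can reproduce; the synthetic
  experiments validate the machinery, not clinical performance.
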