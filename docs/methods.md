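# Methods

`fusmrt` replays, on purely digital phantoms, the measurement chain of an
MR-guided focused-ultrasound (FUS) heating experiment: a phased-array
transducer insonifies a gelatin phantom (optionally through a plastic skull
shell), the deposited acoustic power heats the phantom, a 3D segmented-EPI
MR acquisition encodes the temperature-dependent proton-resonance-frequency
(PRFS) phase into subsampled k-space, and model-based reconstruction
recovers dense temperature maps.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
experiments do and do not demonstrate.

## Acoustic model

**Array.** The therapy transducer is a 256-element phased array on a
spherical cap (1 MHz, 13 cm radius of curvature).  Elements are laid out on
a Fibonacci spiral (area-uniform on the cap; an optional seeded jitter
stands in for the unpublished commercial layout).  Each element radiates a
spherical wave weighted by a piston-like Gaussian directivity whose
effective radius defaults to the radius of a disc tiling the cap area among
the elements.  The directivity matters: isotropic point sources at a pitch
of several wavelengths would scatter most of their power into grating lobes
that a contiguous-element array does not have, which would make a
"source plane carries P watts" normalization meaningless.  With the
directivity, the radiated power stays in the focusing cone and focal
intensity per watt is consistent with the closed-form uniform-bowl result.

**Aperture calibration.** The vendor aperture is not a published number;
the free parameter is fixed by a deterministic 1D root find so that the
water-path lateral pressure FWHM at the geometric focus equals the
transducer's specified 2 mm (computed from the exact free-field summation,
no grid).  The default conditions give an aperture of ≈134 mm.

**Propagation.** The continuous-wave field is marched plane-by-plane along
+z with the hybrid angular-spectrum method: in each Δz step the 2D field is
(i) multiplied in the space domain by the local attenuation exp(−αΔz) and
by the phase deviation exp(i·k0·(c_ref/c −1)·Δz), with normal-incidence
pressure transmission 2Z₂/(Z₁+Z₂) applied where the acoustic impedance
Z = ρc changes between slabs, and (ii) diffracted exactly in the spatial
frequency domain with the homogeneous propagator at the slab's reference
speed c_ref (the sound speed of the slab's dominant compartment), with
evanescent components zeroed for stability.  An optional single backward
sweep accumulates first-order reflections r = (Z₂−Z₁)/(Z₂+Z₁).  The
marched field is the envelope with the carrier exp(i·k̄z) removed; only
magnitudes and relative phases are used downstream.  Lateral grid spacing
must satisfy dx ≤ λ_min/2 (0.74 mm for water at 1 MHz; the default grid
uses 0.7 mm).

Validation: the on-axis field of a focused bowl in lossless water matches
O'Neil's closed form within 3 % of the focal peak over 0.8–1.2 focal
lengths; plane-integrated spectral power is conserved to <0.1 % per plane
in lossless media; a uniform absorbing slab reproduces Beer–Lambert decay
to 10⁻³; a 5 mm PVC slab in gel transmits exp(−2·α_PVC·t)·[4Z₁Z₂/(Z₁+Z₂)²]
of the incident intensity to 4 significant digits.

**Power deposition.** Q = α|p|²/(ρc) (twice the attenuation coefficient
times the time-averaged intensity), i.e. all attenuation is treated as
absorption; scattering is not modelled.

**Aberration correction.** Each element is propagated alone (unit
amplitude, zero phase) through the heterogeneous grid; the corrected drive
phase is −arg p_i(focus), which maximizes |Σᵢ pᵢ(focus)|.  Elements are
marched in batches, so the correction costs one multi-channel simulation.
In a homogeneous medium the corrected phases agree with the geometric
path-length phases to <0.05 rad (up to an irrelevant global constant).

## Phantoms

Two phantoms mirror the physical experiments: a homogeneous 250-bloom
gelatin block (c = 1553 m/s, α = 0.06 Np/(cm·MHz), ρ = 1057 kg/m³,
C_t = 3635 J/(kg·°C), k = 0.55 W/(m·°C)) coupled through a water bath, and
the same block containing a PVC skull shell (c = 2376 m/s,
1.50 Np/(cm·MHz), ρ = 1200 kg/m³) modelled as a spherical-cap shell
concentric with the intended focus, with thickness varying smoothly between
4 and 7 mm over polar angle and azimuth — enough to impose several radians
of phase aberration across the aperture.  Water and PVC thermal properties
default to gelatin's k and ρC_t (heating is only evaluated in the gel; the
choice is config-overridable).  The default grid is 128×128×96 voxels at
0.7×0.7×1.0 mm starting 58 mm from the transducer apex, which puts the
geometric focus 70 mm deep in the gel; neither the phantom dimensions nor
the focal depth are published, so both are configuration, not constants.

**Sonication power.** The printed drive powers (40 W/28.7 s homogeneous,
125 W/23.9 s skull, plus the low-power protocols) reproduce far more than
the measured 22.0 °C peak rise if taken as ideal radiated acoustic power.
A coupling-efficiency factor (default 0.34) scales the nominal power to the
simulated source-plane power; it was fixed once so the 40 W homogeneous
sonication peaks near the measured 22 °C, and is plausible as a combined
electro-acoustic/coupling efficiency.  With it the 125 W skull sonication
peaks near 17 °C (measured: 11.9 °C — the difference tracks how strongly
the shell attenuates, see Limitations).

## Thermal model

The temperature rise obeys the Pennes bioheat equation
ρC_t ∂T/∂t = ∇·(k∇T) − W·C_b(T − T_blood) + Q, discretized with a 7-point
flux-form stencil using harmonic-mean face conductivities (flux continuity
across material interfaces) and forward-Euler time stepping.  Sub-steps are
chosen automatically below half the FTCS stability limit
ρC_t/(2k·Σ1/dᵢ² + W·C_b) (2.255 s at the MR voxel size, ≈0.69 s on the
0.7 mm simulation grid), and every schedule on/off edge and frame time is
hit exactly.  Boundaries are Dirichlet ΔT = 0 (the phantom stays at ambient
far from the focus); insulated zero-flux boundaries are available for
conservation checks, under which total thermal energy is conserved to
round-off.  Phantom perfusion is zero (gelatin is unperfused); W, C_b and
T_blood remain available for in-vivo-style scenarios.  Closed-form checks:
adiabatic linear rise (exact), perfusion-only exponential decay
(τ = ρC_t/WC_b = 533.6 s at W = 2 kg/(m³·s), matched to 1 %), and Gaussian
variance growth σ²(t) = σ0² + 2(k/ρC_t)t (matched to 2 %; the discrete
flux-form stencil grows the second moment at exactly the continuum rate).

## MR acquisition model

Temperature maps enter the MR signal through the PRFS relation
Δφ = γ·α·B0·TE·ΔT with α = −0.01 ppm/°C, B0 = 3 T, TE = 11 ms
(−0.0883 rad/°C; 10 °C ↔ −0.8828 rad).  A synthetic baseline provides the
complex anatomy: compartment signal levels (water 0.85, gel 1.0, PVC 0.05)
under a smooth radial coil shading, and a seeded low-order polynomial
background phase.  Acquisition is snapshot encoding: a centered orthonormal
3D FFT evaluated at each dynamic's k-space-center time (segmented-EPI
sampling assigns the measured temperature to the time the center of k-space
is crossed, halfway through the 2.4 s/4.8 s acquisition).  Subsampling acts
on the kz (slice) direction only — readout kx and in-plane ky are fully
sampled — with a two-tier variable-density pattern: a fully sampled central
band takes ~20 % of the round(nz/R) line budget, the rest is spent on
equally spaced outer lines whose offset rotates with the dynamic index
(complementary interleaving); line trimming at the extremes keeps the
budget exact, so the outermost corners of kz may never be sampled.  Each
echo train's kz indices form an arithmetic progression (constant echo
spacing).  Complex white Gaussian noise (per-channel sd defaulting to 1/30
of the gel magnitude, i.e. focal SNR ≈ 30) is added on sampled points only.
No phase unwrapping is performed anywhere; the protocols in scope keep
|Δφ| < π (22 °C → 1.94 rad), and exceeding that range raises a warning at
encode time.  No field drift is simulated.

## Reconstruction

All methods compute temperature from the phase difference against the
pre-heating baseline image via complex-conjugate multiplication.

* **Fully sampled reference** — centered inverse FFT.
* **Sliding window (view sharing)** — per frame, each k-space location
  takes its most recently acquired value (current frame preferred);
  locations never sampled fall back to the baseline's k-space.
* **MPF (model predictive filtering)** — per frame, the bioheat model
  advances the current temperature map over the inter-frame interval using
  the deposition map Q (scaled by the power schedule); the predicted map is
  converted to phase, combined with the previous frame's magnitude into a
  predicted complex image, and its FFT fills the unsampled k-space
  locations.  Acquired samples are kept bit-exactly (hard data fidelity).
  Voxels with numerically zero deposition get Q = k = W = 0 in the model,
  so the prediction carries the previous frame there and the method behaves
  as a sliding window off-focus.  The support threshold matters: masking at
  percent-level Q fractions insulates the focal region in the thermal model
  (zero-conductivity faces at the support edge) and destroys accuracy; the
  default threshold is 10⁻⁶ of max Q, i.e. only the truly beam-free region
  is frozen.  The model grid is the image grid (no resampling), and the
  bioheat prediction runs at acquired resolution; zero-filling is applied
  for display and metrics only.
* **TCR (temporally constrained reconstruction)** — gradient descent with
  backtracking on C(m) = Σ_t‖mask·F(m_t) − d_t‖² +
  λ·Σ√(|m_{t+1}−m_t|² + ε²), initialized from the sliding window; λ
  defaults to 0.1× the median acquired magnitude, ε = 10⁻⁶.  The cost trace
  is recorded and asserted non-increasing.

## Q/k estimation from a low-power sonication

The pre-treatment fit assumes a separable-Gaussian focal deposition.  Two
closed-form estimators initialize a joint fit: (1) early rise — from the
first heated frame, Q̂ = ρC_t·ΔT(t₁)/t₁, Gaussian-fitted to give (q0,
center, σ); with gelatin conductivity and t₁ = 2.4 s this underestimates
q0 by ~20–25 % (conduction during t₁), measured and documented rather than
ignored; (2) cooling variance growth — per-axis Gaussian-fitted variances
of the post-sonication profile regressed against time (slope = 2k/ρC_t),
which overestimates k by ~15 % for the same reason (the profile is not yet
Gaussian when cooling starts).  The default joint refinement then runs
nonlinear least squares of (q0, center, σ, k) against the closed-form
heat-kernel solution for a Gaussian source in an infinite conducting
medium, evaluated by fixed-order quadrature in elapsed time.  On
finite-difference-generated data with 0.1 °C noise (focal SNR ≥ 20) all
parameters are recovered within 10 % (typically within 4 %) across 20
seeds, provided the lateral grid resolves the focal σ (0.5 mm spacing for
σ = 1 mm; at 1 mm spacing discretization biases q0 by ~10 %).  Fixing q0
high (the +25 % scenario) makes the constrained refit absorb the error
into a higher k and slightly narrower σ — a deposition/conductivity pair
still consistent with the observed heating, which is why the
model-predictive reconstruction is insensitive to that mis-specification
(RMSE shift ≲0.05 °C, bound 0.3 °C).

## Evaluation protocol

The fully sampled, noiseless truth reconstruction (4.8 s dynamics) is the
reference; the subsampled reconstructions (2.4 s dynamics) are linearly
interpolated per voxel to the truth k-space-center times (end queries clamp
to the nearest frame).  Both series are zero-filled (symmetric k-space
padding, amplitude-preserving) to 0.5 mm isotropic before computing: RMSE
at the hottest truth voxel (HV); RMSE over all voxel-time pairs whose truth
rise exceeds 15 % and 85 % of the hottest truth voxel over all frames (a
per-frame-mask variant exists behind a flag); FWHM of focal profiles by
linear interpolation between samples; and per-axis argmax offsets (ties
broken by lowest lexicographic index).  Metrics are restricted to a z-slab
of ±22.5 mm about the intended focus, emulating the reduced slice coverage
of the fully sampled truth protocol (45 mm); without this the skull
phantom's evaluation would anchor to the heated shell itself, which the
truth acquisition never covered.  Mean ± SD across the three seeded repeats
are sample statistics.

## Default study conditions and measured results

At the defaults (128×128×96 grid, 40 W/28.7 s, R = 7, focal SNR 30, three
repeats) the homogeneous experiment yields MPF RMSEs of ≈0.3 °C (HV),
0.17 °C (15 %) and 0.24 °C (85 %), and the skull experiment ≈0.17–0.18 °C —
comfortably below the ≤1.1 °C accuracy the physical experiments
established.  Hottest-voxel and argmax-Q localization agree with truth to
≤0.5 mm per axis (one zero-filled voxel) in both phantoms.  Focusing
through the shell with corrected phases retains ≈16 % of the shell-free
focal intensity (an ≈84 % drop), consistent with the product of two-pass
PVC absorption and the two interface transmissions.  A full experiment runs
in ≈2–3 minutes on one CPU core; the problem sizes above were chosen so the
complete replication stays at desk scale.

## What the synthetic experiments do not show

* **Snapshot encoding.**  Each dynamic sees a frozen object; intra-frame
  heating, T1/T2* evolution, EPI distortion and multi-coil effects are not
  modelled.  Agreement here shows the reconstruction chain is correct, not
  that those confounds are harmless.
* **Generator/model affinity.**  The MPF model uses the same bioheat solver
  as the truth generator (by design — the spec'd pipeline), so the headline
  RMSEs quantify subsampling, noise and interpolation error, not
  model-misspecification error.  The mis-specification experiments (Q×1.25
  with refit k; Q and k independently mis-scaled) probe that separately.
* **TCR on monotone heating.**  The temporal smoothed-L1 cost is nearly
  flat between the sliding-window staircase and the true monotone heating
  trajectory (total variation is invariant under redistributing monotone
  increments), so TCR stays near its initialization and inherits its
  outer-kz staleness lag at the hottest voxel (~4.6 °C HV RMSE at R = 7,
  versus 0.78 °C for MPF with a deliberately mis-specified model).  The
  advantage TCR showed on scanner data is not reproduced under snapshot
  encoding with kz-only variable-density masks; here TCR's measurable
  benefit is denoising relative to the sliding window.
* **Scale anchors.**  The coupling efficiency and the aperture are
  calibrated to two printed numbers (22 °C peak, 2 mm focal width); the
  absolute Q magnitudes are therefore self-consistent SI values, not
  independent predictions.
* **Skull realism.**  The PVC shell is homogeneous with smooth thickness
  variation; real skull has cortical/trabecular structure, stronger
  refraction and shear conversion, none of which are modelled (nor were
  they in the physical phantom).
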