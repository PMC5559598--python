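# Methods

This note documents the models implemented in `dcmrf`, the defaults chosen
where the underlying experimental protocol leaves freedom, and what the
synthetic studies do and do not demonstrate.

## Dual-agent relaxation model

The core assumption is fast-exchange, dilute-solution relaxation: each agent
contributes additively and linearly to both relaxation rates, with no
agent–agent interaction,

R1 = R1₀ + r₁A[A] + r₁B[B],  R2 = R2₀ + r₂A[A] + r₂B[B].

Units are ms, ms⁻¹, mM and mM⁻¹ms⁻¹ throughout (literature relaxivities in
s⁻¹mM⁻¹ divide by 1000). The model is expected to hold for moderate
concentrations; at high local concentrations agents compete for water
coordination and the linearity degrades — nothing in the package models
that regime. Three or more agents make the 2×2 system underdetermined and
are out of scope.

The inversion divides by the relaxivity determinant `det = r₂A·r₁B − r₁A·r₂B`.
With the default Gd/Mn parameter sets |det| ≈ 6×10⁻⁴ mM⁻²ms⁻²; a configurable
guard (default 10⁻¹²) rejects algebraically degenerate pairs, and a unit test
documents that concentration error under a fixed rate perturbation grows as
|det| shrinks. Negative concentrations are legitimate outputs when noisy
measurements are inverted; they are preserved for statistics and clamped only
on explicit request (map export clamps by default, ROI statistics never do).

Relaxivity calibration is ordinary least squares of rate on concentration
(scipy's linear regression); r² is the squared Pearson correlation and the
p-value is two-tailed from the t distribution with n−2 degrees of freedom.
The intercept is fitted freely (standard practice); a fixed-intercept mode
pinning the intercept to a separately measured baseline rate is provided for
comparison.

## Relaxometry simulation

The benchtop arm uses textbook signal models: signed inversion-recovery
`S(TI) = M0(1 − 2β·e^(−TI/T1))` with inversion efficiency β (default 1), and
mono-exponential echo decay `S(t) = M0·e^(−t/T2)`. Signed (not magnitude)
IR signals avoid the sign-ambiguity of magnitude fitting. Noise is additive
zero-mean Gaussian on the amplitudes, the standard thermal-noise model; its
sd is expressed as a fraction of M0.

Defaults where the bench protocol is unspecified: 7 inversion times
log-spaced from 50 ms to 3× the longest expected T1 (default 4500 ms);
CPMG with 1000 echoes at 1 ms spacing. Both are configurable, and the
conventional-MRI variant (8 inversion times / 8 echo times) is just a short
schedule. T1 fitting is nonlinear least squares over (M0, β, T1) with
restarts seeded from the zero-crossing; T2 fitting uses a log-linear fit of
the positive echoes only to initialize a nonlinear fit on the raw
amplitudes, which is unbiased under additive noise where the plain
log-transform fit is not. Repeated measurements (default 2 for T1, 3 for
T2) are fitted independently and averaged.

## FISP-MRF engine

The fingerprinting acquisition is simulated per voxel with the extended
phase graph (EPG) formalism: configuration states F⁺(k), F̄⁻(k), Z(k) over
dephasing orders k, with per-TR RF mixing, relaxation, and a one-order shift
from the unbalanced FISP gradient. The echo is the F0 state decayed to the
echo time; the unit of gradient dephasing accrues after the echo, where the
readout gradient's net moment is no longer zero. RF phase is constant (no
RF spoiling), the inversion preparation is an ideal 180° with configurable
efficiency, and the prep delay (default 21 ms) precedes the first
excitation.

For this discrete-gradient model the EPG recursion is *exact* once the
truncation order exceeds the pulse count, which is how the test suite checks
it: an independently written isochromat Bloch simulator with evenly spaced
dephasing angles agrees to machine precision on short schedules, far inside
the 1% acceptance band. The default truncation (100 orders) was verified
against converged references to change signals by <0.1% even in the
worst case simulated here (T1 4500 / T2 3000 ms over 3000 excitations);
truncation error falls off steeply at the short T2 values contrast agents
produce.

The default schedule emulates the published acquisition's envelope: 3000
excitations, baseline TR 12 ms with a smooth positive pseudo-random
perturbation ≤3 ms, flip angles in repeating 200-excitation half-sinusoid
lobes with alternating pseudo-random peaks ≤75°, echo time 2 ms. The true
vendor waveform is not public, so the generator is seeded and serializable:
any published FA/TR train can be loaded from JSON and used identically.

The dictionary grid reproduces the published piecewise spacing (T1 10–4500
ms in 4 segments, T2 2–3000 ms in 6 segments; 105×100 axis values, shared
boundaries counted once). "All logical combinations" is interpreted as the
Cartesian product with unphysical T2 > T1 pairs removed by default (8542
retained atoms); the unfiltered product is available by flag. Matching
maximizes |⟨atom, signal⟩| over unit-norm atoms — complex inner product with
magnitude maximization, so matching is invariant to global scale and global
phase — with ties broken toward the lowest atom index (atoms sorted by T1
then T2) for bit-reproducible maps. Zero-norm signals are flagged as
background, not errors.

## Digital phantoms

The 17-vial phantom provides ground truth for every stage: 5 Gd-only vials
(0.05, 0.1, 0.2, 0.35, 0.5 mM), 5 Mn-only (0.0125, 0.025, 0.05, 0.1,
0.2 mM), 6 mixtures evenly spaced across Gd 0.025–0.355 / Mn 0.00625–0.15
mM, and one water-only vial, laid out in four rows (mixtures on the top two
rows, Mn-only third, Gd-only bottom). The single-agent series and the
mixture endpoints are pinned to the published ranges; intermediate mixture
values are representative, and user tables load from CSV. The default
canvas is 128×128 (full 352×352 available by config) with circular vials;
per-repeat repositioning is a rigid integer translation (default ±2 px).

Series noise is stationary complex Gaussian per timepoint with sd =
`noise_sd` × the maximum noise-free signal magnitude, split evenly between
real and imaginary channels — the standard MR thermal-noise model. Coil
sensitivities, B0/B1 inhomogeneity, spiral undersampling and reconstruction
artifacts are deliberately not modeled: simulated signals are clean
per-voxel evolutions plus noise. Passing tests therefore demonstrate the
correctness of the model, the simulator, the matcher and the inversion —
not robustness to the artifact structure of accelerated in vivo
acquisitions.

## Pipeline and statistics

The study driver follows the bench protocol: baseline (T1₀, T2₀) is taken
from the matched water vial of the same modality, never mixed across
modalities; in `"fit"` mode the relaxivities are re-estimated from the
phantom's own single-agent vials (ROI-mean rates regressed on
concentration); concentrations are computed per repeat and then averaged,
not computed from averaged T1/T2 maps. Vial comparisons use the unpaired
two-tailed t-test, equal-variance by default with Welch behind a flag. ROI
statistics exclude no-signal pixels and silently omit labels with no valid
pixel.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run at desk scale by choice:
the end-to-end replication uses a 96×96 phantom, a 1000-excitation train
and the full dictionary grid (≈25 s); matcher unit tests use an
800-excitation train with the reduced `coarse()` grid (464 atoms). An
800-excitation (~11 s) train is the shortest that reliably encodes the
longest T2 values in the grid — at 400 excitations the noise-free match is
no longer within one grid step at T2 ≳ 450 ms — consistent with
fingerprinting's usual 10–50 s trains. Under these conditions the noise-free
17-vial replication recovers estimated-vs-true slopes of 1.002 (Gd) and
1.000 (Mn) with r² > 0.999, and stays within 0.003 of unity at 1%
measurement noise; dictionary quantization is the dominant error source.

Other numerical defaults: the T2 ≤ T1 filter is applied before simulation;
dictionary atoms with numerically zero norm abort the build with their
(T1, T2) reported; nonlinear fits use bounded Levenberg–Marquardt/TRF with
documented restarts and raise a diagnostic-carrying error rather than
returning silently bad values.

## Known limitations

- Mono-exponential relaxation only; multi-compartment / magnetization-
  transfer effects are not modeled.
- Exactly two agents; the linear system is underdetermined beyond that.
- No B0/B1 field effects, no k-space stage, no reconstruction artifacts.
- Temperature enters only through which relaxivity preset is used.
- The default FA/TR waveform is this package's own documented construction,
  not the vendor sequence; quantitative results transfer only insofar as a
  user supplies their actual schedule.
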