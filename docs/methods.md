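# Methods

## Model and conventions

All quantities use a fixed unit system: times in ms, diffusivities in
μm²/ms, gradient areas as q = γδG in μm⁻¹ (no 2π factor), and diffusion
weightings b = q²(Δ − δ/3) in ms·μm⁻².  In these units the emulated
protocol's numbers are mutually consistent: a per-axis crusher area of
0.023 μm⁻¹ applied on three orthogonal axes at Δ = 400 ms, δ = 2.22 ms
gives a total reference b₀ = 3·q₀²·(Δ − δ/3) ≈ 0.63 ms·μm⁻², and inverting
b = γ²δ²G²(Δ − δ/3) for b = 3.5 ms·μm⁻² reproduces the nominal 157–375 mT/m
gradient amplitudes across Δ = 400–70 ms.  One residual discrepancy is
documented rather than modeled: the protocol's quoted reference b₀ at
Δ = 70 ms (0.117 ms·μm⁻²) slightly exceeds the three-axis narrow-pulse
value (≈0.110); the difference presumably comes from imaging-gradient
details that are not reconstructable from the protocol description, so the
schedules here use the analytic values throughout.

### Reference schedules

Both reference designs are pinned at the longest diffusion time: with
q₀,Δmax = sqrt(b₀,Δmax / (n_axes·(Δmax − δ/3))),

- fixed-b₀: b₀(Δ) = b₀,Δmax constant, q₀(Δ) ∝ (Δ − δ/3)^(−1/2);
- fixed-q₀: q₀(Δ) = q₀,Δmax constant, b₀(Δ) ∝ (Δ − δ/3).

The two coincide at Δmax by construction.  A schedule is undefined beyond
its calibration point, and this is enforced.

### Two-point ADC and the ordering of schemes

ADC = −ln(S/S₀)/(b − b₀), with the sign chosen so attenuating signals give
positive diffusivities.  For a fixed direction both the measurement and the
reference sample one decay curve S(b), as in the two-point-fit geometry the
comparison is about.  Consequences that the test suite asserts: the
mono-exponential ADC is invariant to (b, b₀); for any model with two
distinct diffusion coefficients the ADC decreases with b₀ (convexity of
the mixture of exponentials); fixed-b₀ curves are flat in Δ for
Δ-independent tissue while fixed-q₀ curves decline; and since fixed-b₀
carries the *larger* b₀ at every Δ < Δmax, the ordering is
ADC_fixed-b₀ ≤ ADC_fixed-q₀ ≤ ADC_true, with the first pair equal at Δmax.
The headline difference metric is
(ADC_fixed-q₀ − ADC_fixed-b₀)/ADC_true × 100 %.

The reference attenuation in these analytic curves is deliberately applied
along the measurement direction.  The physical single-reference acquisition
applies crushers on three axes at once, which attenuates an anisotropic
tissue differently than the measurement direction does (directional bias);
that acquisition artifact is reproduced by the phantom generator, which
uses the true three-axis reference wave-vector, but is kept out of the
analytic scheme comparison, where it would conflate two separate effects.

### Tissue models

- **Biexponential**: E(b) = f_s·e^(−b·D_s) + (1 − f_s)·e^(−b·D_f).
  Defaults f_s = 0.3 (slow fraction), D_s = 0.2, D_f = 1.0 μm²/ms.  The
  literature this emulates is ambiguous about whether the quoted fraction
  (0.3 vs 0.33) refers to the fast or slow pool; the slow-pool reading with
  f_s = 0.3 is the default and both the value and referent are plain
  constructor arguments.
- **Gaussian tensor**: E = exp(−B:D) with the full 3×3 b-matrix; used for
  hindered compartments and tensor phantom regions.
- **Two-compartment cylinder**: intracellular fraction f_i = 0.8 inside
  impermeable parallel cylinders (radius r = 5 μm, D_i = 2 μm²/ms), free
  along the axis and restricted transversely; extracellular pool isotropic
  Gaussian with D_h (default 2 μm²/ms).  Anisotropy of the extracellular
  space is out of scope.

### Restricted propagator

The transverse signal uses the narrow-pulse eigenfunction expansion of the
reflecting-disk propagator:

E(q, Δ) = [2J₁(qr)/(qr)]² + Σ_{n,k} c_n · W_nk(qr) · exp(−β_nk² D Δ/r²),

with β_nk the k-th positive root of J_n′, c₀ = 1, c_n = 2 for n ≥ 1 and

W_nk = [2 qr J_n′(qr)/((qr)² − β_nk²)]² · β_nk²/(β_nk² − n²).

All decaying weights are positive (β_n1 > n for roots of J_n′), so E is
monotone non-increasing in Δ; the weights sum to 1 at Δ = 0 (checked to the
truncation level), the Δ → ∞ limit is the squared disk form factor, and the
small-q long-time ADC reduces to r²/(4Δ).  The root table defaults to 30
angular orders × 50 roots, sufficient for qr ≲ 22 and D·Δ/r² ≳ 10⁻²; a
computed tail bound raises a diagnostic error outside that regime instead
of silently returning a truncated value (callers can request deeper
tables).  Exact resonances qr = β_nk are removable singularities handled by
an epsilon guard.  Within the pipeline, Gaussian factors use the exact
pulsed-pair b = q²(Δ − δ/3) and the propagator is evaluated at the same
effective time Δ − δ/3, so the Gaussian limit of the cylinder model is
consistent with the b-value convention (and coincides with the narrow-pulse
time as δ → 0; at the protocol's δ = 2.22 ms the distinction is below 1 %).

The original analyses this package re-derives were run with a general
matrix-formalism simulator under the same narrow-pulse assumption; here the
analytic series plays that role and is validated independently.

### Monte Carlo oracle

`mc_validation` is a deliberately separate implementation: Gaussian steps
of variance 2D·dt per axis, uniform initial positions, specular reflection
at the circle (crossing point solved exactly per step, mirrored across the
local tangent, iterated for rare double crossings).  The stability bound
dt ≤ r²/(100·D) keeps the RMS step below ~0.14 r; the default is
r²/(200·D).  The signal estimator is |⟨e^(iq·Δx)⟩| with a 20-batch
batch-means standard error.  The suite checks the Einstein relation, the
uniform-disk displacement plateau (total MSD → r²), closed-form free and
long-time limits, 1/√n shrinkage of the SE, and agreement of the analytic
series with the oracle within 3 SE on a 12-point (q, Δ) grid with 10⁵
walkers.  The two-compartment perpendicular attenuation at the b = 4,
Δ = 400 ms working point is regression-locked to an oracle run
(E = 0.7512 ± 0.0002, 10⁵ walkers, seed 20260901).

### STEAM amplitude and noise

S = ½·S_base·e^(−τ_m/T1)·e^(−TE/T2)·E with τ_m = Δ − TE/2 (symmetric
encode/decode; the emulated protocol never states the mapping explicitly
and this is the standard choice).  Defaults: T1 = 600 ms (the estimate for
the emulated fixed postmortem tissue), T2 = 50 ms (a plausible postmortem
white-matter value at high field; it only scales amplitudes and cancels in
every ADC because both measurements at one Δ share it — an invariance the
tests assert for T1 ∈ {300, 600, 1200} ms).

Noise is Rician: the magnitude of (S + n₁, n₂) with n₁, n₂ ~ N(0, σ²),
seeded.  σ is specified directly or via an SNR referred to the
unattenuated white-matter STEAM amplitude at the shortest diffusion time
(default SNR 30; the emulated experiment never states its SNR).  The
high-SNR mean S + σ²/(2S) is verified against 10⁵ draws.

### Effective waveforms and b-matrices

Waveforms are piecewise-constant effective gradients over the stimulated
pathway: events before storage carry pathway sign +1, events after recall
−1, and the effective gradient is identically zero during the mixing
interval (events inside it are rejected).  The b-matrix
B = ∫F(t)F(t)ᵀdt, F = ∫G_eff, is integrated analytically over constant
segments — exact for rectangular lobes, so the ideal-pair trace matches
q²(Δ − δ/3) to rounding.  Finite ramps are ignored (ideal rectangles with
nominal areas).  The conventional crusher layout plays the crusher pair
with slice-select polarity, leaving a net area q_c + q_s across the mixing
interval whose b-value grows with Δ; the modified layout flips the
crushers so each pairs with its adjacent slice-select lobe, and the
imaging-gradient b-value becomes exactly Δ-invariant for q_c = q_s
(the default 0.046 μm⁻¹ each).  Lobe placements inside the half-echoes are
fixed small offsets (0.5 ms imaging lobes); they affect the constant part
of the imaging b-value, not any of the Δ-dependence properties.

### Phantom and problem sizes

The default phantom is a 32×24×5 grid at 0.4 mm isotropic — a scaled-down
matrix chosen so a full simulate-and-analyze cycle runs in seconds on a
laptop while keeping thousands of voxels per region; the acquisition-sized
64×48×5 grid is a config change.  Regions are y-axis bands: central WM
(cylinder tissue, fibers along x), flanking GM (biexponential), zero-signal
background.  Region signals are spatially uniform by construction, so the
generator evaluates one signal per (region, volume) and broadcasts before
adding voxelwise noise.  Volume ordering is: for each Δ ascending, the
reference volumes (fixed-b₀ then fixed-q₀), then the 30 directions; all
metadata travels in a JSON sidecar, and analysis is invariant to volume
permutation.  What the phantom does *not* emulate: k-space effects (Gibbs
ringing, tapering), partial-volume mixing at region borders, spatial T1/T2
variation, per-direction reference acquisitions, and exchange between
compartments — so passing tests demonstrate correctness of the estimation
chain under the stated signal model, not robustness to those
acquisition-physics effects.

### Tensor fitting

Weighted log-linear least squares of ln S against the six unique b-matrix
elements plus an intercept, weights S² (first-order variance stabilization
for log-transformed magnitudes), one pass.  At least 7 volumes including a
reference are required; a rank check rejects degenerate direction sets
(≥7 well-spread directions are needed — 6 quasi-uniform directions plus one
three-axis reference are provably rank-deficient).  Eigenvalues are sorted
descending, negative ones clamped to zero with the voxel flagged, and
eigenvectors signed so their first nonzero component is positive.  Voxels
with any nonpositive signal are excluded and flagged.  Masks follow the
emulated analysis: WM = FA > 0.20, GM = MD > 0.4 μm²/ms outside WM,
restricted to the nonzero-signal support.

### Time-dependence summary

ΔADC% = 100·(ADC(70) − ADC(400))/ADC(70) per scheme, and the added
dependence of fixed-q₀ over fixed-b₀ as (ΔADC_q₀ − ΔADC_b₀)/ΔADC_b₀·100.
The normalization of that third column is not uniquely pinned down by the
summaries it emulates; the alternative denominator ΔADC_q₀ is available
via ``denominator="fixed_q0"``.  When the fixed-b₀ dependence is
numerically zero (an unrestricted phantom), the ratio is reported as-is
and is meaningless noise — the per-scheme ΔADC% columns are the meaningful
output there.

## Known limitations

- The restricted propagator is narrow-pulse only; finite-δ corrections
  (relevant for δ ≳ Δ/10) are out of scope, as is the general
  matrix-formalism engine for arbitrary waveforms.
- No exchange/permeability, no radius distributions, no fiber dispersion.
- The Monte Carlo reflection is first-order in the step length; it is
  validated only within the stability bound.
- Added-dependence percentages are ratios of differences and inherit large
  relative errors when the denominator dependence is small.
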