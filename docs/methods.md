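# Methods

This note documents the physical model, the numerical conventions, and the
design decisions behind `phasetomo`, in enough detail to reproduce or audit
any stage.

## Forward model and conventions

A thin object multiplies the incident wave by the transmission function
T(x) = exp((B + i)·φ(x)). The phase φ is non-positive for matter denser than
vacuum (retarded wave), and B = β/δ ≥ 0 couples attenuation to phase under
the homogeneous ("single-material") object assumption, so |T| = exp(Bφ) ≤ 1.

Free-space propagation over a distance with per-pixel Fresnel number
F = Δx²/(zλ) is the Fourier multiplier

    H(ν) = exp(−i χ(ν)),   χ(ν) = π (νx²/fx + νy²/fy),

with ν in cycles/pixel on the standard DFT grid (`numpy.fft.fftfreq`) and
per-axis Fresnel numbers (fx, fy) to support astigmatic magnification.
The operator is exactly unitary on the discrete grid — energy conservation,
invertibility and the composition law 1/f = 1/f₁ + 1/f₂ hold to machine
precision and are asserted in tests. Boundaries are periodic (optional edge
padding for simulating non-periodic scenes). The kernel warns when its
highest frequencies are aliased relative to the continuous propagator; the
discrete model itself remains consistent, which is what the self-consistency
(simulate → retrieve) tests rely on.

The sign of the exponent is a package-wide convention. Linearizing
|P(exp((B+i)φ))|² for weak φ under this convention yields the contrast
factor

    F(I − 1)(ν) = 2 s(ν) F(φ)(ν),   s(ν) = sin χ + B cos χ,

which ties every retrieval filter to the propagator. A dedicated test checks
this linearization at max|φ| = 10⁻³ to better than 1% — the guard against
sign/scale errors.

Cone-beam data at magnification M = z02/z01 are treated in the effective
parallel geometry of the Fresnel scaling theorem: pixel Δx/M, distance
z01·z12/z02. For M ≈ 300–400 this is the standard approach; no cone-beam
(FDK) reconstruction is implemented. Internally everything is SI; the
constructors take mm/µm/keV. The energy–wavelength constant is
hc = 12.3984193 keV·Å. Printed magnifications are rounded half-away-from-zero.

## Direct-contrast filters

All four single-distance filters are closed-form in Fourier space, written
in (cycles/pixel, Fresnel-number) units:

* **Paganin**: φ = ln(F⁻¹[F(I)/(1 + χ/B)])/(2B). Exact for slowly varying
  single-material objects; the low-pass denominator suppresses fringes.
* **Generalized Paganin** replaces χ by its discrete-Laplacian counterpart
  χ_d(ν) = [(1 − cos 2πνx)/fx + (1 − cos 2πνy)/fy]/(2π). The constant is
  fixed by the small-ν limit (1 − cos 2πν = 2π²ν² − O(ν⁴), so χ_d → χ with
  an O(ν⁴) defect); tests verify the limit, the weaker Nyquist damping, and
  the ~4× shrinkage of the classic/generalized discrepancy per 2× grid
  refinement.
* **Modified Bronnikov**: φ̂ = F(I−1)/(2χ + α), the weak pure-phase limit
  (2 sin χ ≈ 2χ) with a dimensionless α (default 10⁻³) filling the DC
  singularity. Consequences, documented and tested: the retrieved mean is
  arbitrary, and spatial frequencies with 2χ ≲ α are attenuated. The
  filter-mismatch error balance α/(2χ) + χ²/6 is minimal near χ ≈ (3α/2)^⅓;
  accuracy claims therefore refer to mid-frequency object content and
  zero-mean comparisons.
* **Bronnikov-aided correction** divides I by the phase-contrast factor
  1 + γ·F⁻¹[2χ·F(φ_MB)], γ ∈ [0, 1], denominator clipped at 0.1 (with a
  warning) to avoid blow-ups where the linear model overshoots. Because the
  Bronnikov phase estimate folds the absorption contrast into its
  low-frequency content, the correction also flattens slow absorption
  variations — the filter is a fringe remover, not a quantitative
  attenuation retrieval, and its test measures edge-fringe suppression.

## Holographic-regime methods

**CTF.** Multi-distance regularized least squares on the linear model:
F(φ) = Σ_d s_d·F(I_d−1) / (2 Σ_d s_d² + α(ν)), a single closed-form step.
The two-level regularization α(ν) blends a low-frequency weight α_low into a
high-frequency weight α_high with an erf crossover centred at χ = π/2 (the
first CTF maximum) of width 0.5 in χ — a function of χ, not |ν|, so it
remains consistent under astigmatism. The default weights are
α_low = 2×10⁻⁵, α_high = 3×10⁻⁵ on a scale where s² ∈ [0, 1+B²]; the
denominator's factor 2 fixes that normalization. Multi-distance stacks must
already be rescaled to a common pixel grid (`geometry.rescale_fresnel`);
there is no in-retrieval registration.

**Constrained CTF.** The same quadratic under pixelwise constraints
(non-positivity, bounds, finite support), split by ADMM: the x-update is
Fourier-diagonal and closed-form, x̂ = (Σ s_d Î_d + ρ v̂)/(2Σs² + α + ρ);
the z-update is the exact Euclidean projection onto the constraint set. The
final z iterate is returned, so constraints hold exactly (not just in the
limit). Accelerated ADMM with restart (momentum reset when the combined
residual fails to decrease by η = 0.999) and optional residual balancing
(ρ ×2/÷2 when primal/dual residuals diverge by 10×); ρ defaults to 1.

**Nonlinear Tikhonov.** For strong phases the linearization fails; the
functional

    J(φ) = Σ_d ½‖ |P_d(exp((B+i)φ))| − √I_d ‖² + (1/2N)‖√α(ν)·F(φ)‖²
           [+ τ Σ √(|∇φ|² + ε²)]

is minimized by the adaptive proximal gradient method with the constraint
projection as prox, warm-started from the (projected) CTF solution. The
data term compares amplitudes, not intensities — a deliberate convention
(better-conditioned gradients at low counts) that may differ numerically
from implementations using the intensity residual. Gradients are
hand-derived closed forms (the propagator's adjoint is its inverse):
grad = Σ_d Re[conj(P_d⁻¹((|ψ_d|−√I_d)·ψ_d/|ψ_d|))·(B+i)·T] + F⁻¹[α F(φ)],
plus the standard −div(∇φ/√(|∇φ|²+ε²)) term for the smoothed TV option
(forward differences, periodic). A central-finite-difference checker
validates them to 10⁻⁵ in tests. τ = 0 reduces exactly to plain Tikhonov;
ε (default 10⁻³) keeps the TV term smooth so the same solver applies.

**Alternating projections.** Classic modulus-replacement iterations between
the measurement sets {|ψ_d| = √I_d} and the homogeneous-object manifold,
averaging the back-propagated planes uniformly (the per-distance weighting
is a free choice; uniform is used). The object step extracts φ by the real
least-squares projection φ = (B·Re log T̄ + Im log T̄)/(1+B²) and applies the
constraints. Like the other iterative methods it warm-starts from the CTF
solution; convergence of the magnitude residual is reported per iteration.

## Solvers

`pgm_adaptive` uses Barzilai–Borwein (BB1) spectral steps with a nonmonotone
backtracking line search over a 10-iteration window. The acceptance rule is
the majorization condition f(x⁺) ≤ max(last 10 f) + ⟨∇f, x⁺−x⟩ +
‖x⁺−x‖²/(2·step): a pure descent condition on the smooth part alone would be
unsatisfiable whenever the prox must climb the smooth term (projection onto
an active constraint). Initial steps come from a secant estimate of the
local Lipschitz constant. Default tolerance 10⁻⁶ relative iterate change,
100 iterations. `fista` implements Nesterov momentum
t_{k+1} = (1+√(1+4t_k²))/2 with gradient-mapping adaptive restart and
optional backtracking. `check_grad` probes random directions with central
differences (step 10⁻⁶ × scale).

## Preprocessing

Raw frames follow R = dark + flat·signal. Flats are either interpolated
linearly in the scan angle between the averaged empty-beam stacks taken
before and after the scan, or synthesized per frame from a PCA basis: the
mean flat plus the leading K left-singular images of the centered empty
stack, coefficients fitted by least squares on an object-free region.
Faulty pixels are flagged at k = 6 robust standard deviations
(1.4826 × MAD) of the residual against the 3×3 median and replaced by that
median; the 1-px border is never flagged (ill-defined window), and the
repair is idempotent. Low-frequency background is removed by dividing by a
least-curvature estimate: outside the object support a Gaussian-smoothed
(σ = 5 px) copy of the hologram, inside the support its biharmonic
continuation (minimize Σ(Δu)² with the outside fixed), solved as a sparse
linear system; the inpainting direction (estimate the background *inside*
the support from the outside) resolves an ambiguity in how the procedure
can be read, and the degenerate empty-support case is defined as division
by the smoothed hologram.

## Tomography

Conventions: projection stacks are (angle, row v, column u); the rotation
axis is vertical; volumes are (z, y, x); pixel centers at integer
coordinates; the axis crosses the detector at column (N−1)/2 + cor_offset.
Scans cover [0, π) non-redundantly. Per-projection detector shifts, the CoR
offset and a small axis tilt (per-row CoR slope) are modelled as horizontal/
vertical Fourier shifts of the projections — for parallel beams a constant
axis offset is exactly a uniform sinogram shift — and are compensated the
same way before filtering/back-projection, never by resampling.

The projector samples each ray by bilinear interpolation at 0.5-voxel steps;
each angle's sampling is assembled into a sparse matrix, and back-projection
applies its transpose, so the pair is adjoint to machine precision (the
property that makes SIRT a convergent preconditioned Landweber iteration).
Matrices are cached when the estimated footprint is small, rebuilt on the
fly otherwise. FBP uses the discrete ram-lak kernel (transform of the
sampled spatial ramp — sampling |ν| directly would bias the DC level),
optional Shepp–Logan/Hann apodization, zero-padding to 2N, and weight
π/N_angles. The FBP∘project self-consistency on a 256² head phantom with
400 angles measures ≈ 2.8% RMSE of the dynamic range inside the 90%
inscribed circle; this is Gibbs-limited at the phantom's discontinuities
(an analytically exact sinogram reconstructs no better), which bounds what
any test of that form can demand.

## Alignment and ring removal

Subpixel registration is upsampled DFT cross-correlation
(`skimage.registration.phase_cross_correlation`), returning the shift with
the convention reference(x) ≈ moving(x − shift). CoR estimation registers
either one mirrored opposing pair (cor = shift/2; mirroring about the
pixel-center column (N−1)/2 makes this exact) or, for spans > π, whole
mirrored half-sinograms — averaging over all angles, hence robust to jitter;
per-row repeats give the axis tilt by a least-squares line.

Reprojection alignment iterates: reconstruct (FBP) under the current
per-projection shifts → re-project → register each reprojection against its
measured image → add the detected shift (damping 1.0 by default) to that
projection's shift. The loop runs on block-binned (factor 4–8),
Gaussian-high-pass-filtered (σ = 40/binning) copies; detected shifts are
scaled back by the binning factor, and iteration stops when the largest
update falls below 0.1 px. The shift set is only identifiable up to the
gauge of a global object translation — constant vertical offset, and
horizontal components spanned by {cosθ, sinθ} — so recovery error is
quoted after projecting the residual out of that null space, and
reconstructions are compared to ground truth after registering out the
global in-plane translation. On synthetic scans with uniform ±10 px jitter
the residual converges to ≈ 0.1–0.4 px RMS within 50 iterations at
binning 4.

Ring (stripe) removal: the additive filter subtracts the deviation of each
column's angular mean from its moving average (odd width, default 31),
which leaves at most amplitude/width of an isolated stripe. The wavelet-FFT
filter decomposes the sinogram l levels deep (db5 by default; l = 4,
σ = 1 defaults), damps the angle-axis DFT of each level's
vertical-structure band by 1 − exp(−k²/2σ²) with k in band-index units, and
reconstructs. Measured on a synthetic stripe: > 5× suppression with < 2%
RMS change to a stripe-free sinogram.

## Synthetic data

Phantoms (3-D Shepp–Logan ellipsoid table with contrast-enhanced values,
uniform balls) are rasterized by supersampled area sampling, so voxel
values are coverage fractions: resolution-independent, consistent under
grid refinement, and with analytically known projections for the ball
(2√(R²−r²)) used as oracles. The scan simulator projects the δ-volume along
the (optionally jittered) trajectory, scales projections so the stated peak
|φ| is met (default 0.1, weak-object regime), applies the non-positive sign
convention, propagates exp((B+i)φ) to every distance (defaults: B = 0.035,
Fresnel pair 2.44×10⁻⁴/1.98×10⁻⁴ — the reference two-distance conditions),
and applies Poisson noise at `photon_count` photons/pixel (default 10⁴;
`None` = noiseless) plus uniform per-projection jitter. All randomness
derives from one seed; equal seeds give bit-identical scans, and the ground
truth (ideal phase maps, injected shifts, true geometry) is returned with
the holograms.

What the simulations do **not** emulate: partial coherence and source blur,
detector point-spread and nonlinearity, beam-profile drift beyond the
flat-field models, and scattering outside the projection approximation.
Passing tests therefore demonstrate algorithmic correctness under the
stated forward model, not end-to-end performance on any particular
instrument's data.

## Problem sizes and defaults used in validation

Unit tests run at 32²–256² images and 64³–96³ volumes. The headline
end-to-end check simulates a 128³ phantom over 180 angles at the reference
two-distance conditions with ±10 px jitter, retrieves with the CTF, aligns
(binning 4, registration upsampling 50), ring-filters (l = 3, the maximum
db5 depth at 128 columns) and reconstructs with FBP; the mid-slice Pearson
correlation with the phantom is ≈ 0.95 across seeds. With Poisson noise at
the default 10⁴ photons/pixel the same chain is retrieval-noise-limited
(r ≈ 0.88 with plain CTF, ≈ 0.90 with TV-regularized Tikhonov at its
error-minimizing weight τ ≈ 5×10⁻³); the jitter-recovery and end-to-end
checks are therefore run noiseless, isolating the alignment behaviour they
are meant to probe.

## Known limitations

* No cone-beam (FDK) reconstruction; high-magnification data are handled in
  the effective parallel geometry only.
* Phase maps are not unwrapped; strong-phase retrieval relies on the
  nonlinear solver staying in the correct basin (warm start from CTF).
* The Tikhonov α normalization and amplitude-vs-intensity residual are
  package conventions; weights are not numerically interchangeable with
  other toolboxes without rescaling.
* Reprojection alignment estimates rigid per-projection translations only —
  no rotation or magnification drift.
* The biharmonic background solver is dense-matrix sparse-LU per call;
  frames much larger than ~512² will want a multigrid replacement.
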