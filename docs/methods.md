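# Methods

## Signal models

**Geometry and regime.**  A voxel is modeled as a single intracellular
compartment of impermeable cylinders ("sticks with a radius") with
intracellular parallel diffusivity Dc∥ and intrinsic (axoplasm) diffusivity
D₀.  Extra-cellular water is assumed fully suppressed at the b-values used
(≥ 6 ms/µm²), exchange is neglected at diffusion times ≤ 45 ms, and
relaxation weighting is ignored.  All quantities use µm / ms / mT/m units;
b-values are in ms/µm² and the proton gyromagnetic ratio is fixed at
γ = 2.6752×10⁸ rad s⁻¹ T⁻¹.

**Perpendicular attenuation.**  Two models of the signal decay perpendicular
to the cylinder axis are provided: the Neumann long-pulse limit
S⊥ = exp(−κ r⁴) with κ = 7γ²g²δ/(48 D₀), valid for δ ≫ r²/D₀, and the
Van Gelderen Gaussian-phase series over roots of J₁′ (plus its spherical
analogue over roots of j₁′ for cell bodies).  The series uses 20 roots by
default, which holds the truncation error of the exponent below 1e-9 at the
protocol's strongest condition; the original 10-root truncation leaves a
~3e-8 relative residual.  Validity is *flagged*, not enforced: the
long-pulse flag trips when δ < 10 r²/D₀ and the large-bDc∥ (erf ≈ 1) flag
when b·Dc∥ < 6.  These thresholds are package conventions for regimes that
are usually stated only qualitatively.

**RISH forward models.**  Writing t = b·Dc∥, the zeroth- and second-order
rotational invariants of the dispersed-cylinder voxel in the erf ≈ 1 regime
are

    SM(b) = f √(π/(4 Dc∥)) · S⊥(r) / √b
    SV(b) = p₂ · f · (√π/8) · Dc∥^{-3/2} · (2t − 3) · S⊥(r) / b^{3/2}

The SV expression is the exact second-order Legendre projection of the stick
kernel: ∫₀¹ P₂(x) e^{−t x²} dx → −(√π/8) t^{−3/2} (2t − 3) as t → ∞, with
the orientation distribution entering only through its second Legendre
moment p₂.  The (2t − 3) factor changes sign at t = 3/2, so the SV model
refuses evaluation below b·Dc∥ = 3/2.  The perpendicular kernel replaces the
Gaussian radial term e^{−b Dc⊥} of the general rotational-invariant
framework, which is the only modeling change relative to a zero-radius
stick.

**RISH scale convention.**  Per shell, signals are decomposed in a real,
even-order, symmetric SH basis (Lmax = 6 default) and the order-ℓ feature is
Sℓ = ‖c_ℓ‖₂ / √(4π(2ℓ+1)), normalized by the b = 0 signal.  With this scale
S₀ equals the spherical mean of the signal, and the same convention is used
in the SV forward model, so forward and inverse are algebraically
consistent.  Any fixed scale would do — the two-shell ratios cancel it —
but this one makes S₀ directly interpretable.

## Estimators

The two-shell log-linear estimators invert the forward models in closed
form (see README).  Design choices:

* Negative r⁴ (possible under noise) is reported as r = 0 with a
  ``negative_r4`` flag while the raw r⁴ is preserved, so segment-level
  averaging of r⁴ is not censored.
* Non-positive features give NaN with an ``invalid_input`` flag rather than
  an exception, since they occur voxel-wise in noisy maps.
* More than two shells are handled by weighted linear regression of the
  log-transformed feature on κ (the natural generalization of the
  log-linear model); with two shells this reduces exactly to the closed
  form.
* κ is computed per shell from that shell's own (g, δ); shared timings
  across shells are not assumed.
* Dc∥ for the SV path is an input (scalar or per-voxel map); the package
  does not estimate it.
* The nonlinear reference estimator fits (prefactor, r) by bounded
  least squares (r ∈ [0, 10] µm) with multi-start at r₀ ∈ {0.5, 2, 4} µm,
  using either perpendicular model.  On noiseless Neumann data it agrees
  with the log-linear estimator to better than 1e-6; inverting Van Gelderen
  synthesized data with the Neumann model at the default timings biases
  r = 3 µm down by ≈ 1.8% — the cost of the long-pulse approximation inside
  its nominal regime.

**Rician-ML SH fit.**  Coefficients maximize the Rician likelihood with a
known, fixed σ (L-BFGS on the analytic gradient, initialized at the
least-squares solution; predicted signals are clipped at 1e-12 because the
Rician location must stay positive).  At per-direction SNR ≳ 100 the ML and
least-squares fits coincide; at low SNR the ML fit removes most of the
Rician-floor inflation of the ℓ = 0 coefficient.  The SV feature keeps a
positive noise bias regardless (the norm of five noisy coefficients is
noncentral-chi distributed); `sv_bias_probe` quantifies it by Monte Carlo.

## Synthetic data

The generator emulates a strong-gradient five-shell protocol: b = 0.5, 1,
2.5, 6, 30 ms/µm² with 30/30/30/120/240 directions, δ/Δ = 15/30 ms, and
per-shell amplitudes back-computed from b (273 mT/m at b = 30), plus 23
b = 0 volumes.  Direction sets are deterministic spherical-Fibonacci points
rotated by a seed-derived rotation; their even-order SH design matrices have
condition number < 1.8 for n ≥ 60.  Voxel signals are Watson-dispersed
restricted-cylinder mixtures (concentration matched so the ODF's second
Legendre moment equals the requested p₂), optionally mixed with a glia
compartment (isotropic thick processes, or a sphere via the Gaussian-phase
sphere series), under two-channel Rician noise with σ = S(b=0)/SNR.  The
default grid phantom is 10×10×3: radius 1–5 µm × glia fraction 0–0.5 ×
glia kind {none, process, sphere}.

What the generator does *not* emulate: imaging artifacts (motion, eddy,
Gibbs), spatially varying noise, multi-coil (noncentral-chi) statistics,
axonal beading/undulation, exchange, or relaxation differences between
compartments.  Passing tests therefore demonstrate correctness of the
estimation chain under the stated biophysical model, not robustness to
acquisition artifacts.

## Monte Carlo simulator

Walkers take fixed-length 0.40 µm steps with uniformly random orientation;
the time step is tied to the step by the Einstein relation
dt = step²/(6 D₀) ≈ 10.7 µs at D₀ = 2.5 µm²/ms.  Boundaries are impermeable;
a step crossing the substrate surface is specularly reflected (up to 10
bounces per step, after which the residual displacement is dropped — a
sub-nanometre-scale event at these step sizes).  Substrates are watertight
unions of spheres and capped cylinders; the union exit point is found
analytically per primitive and validated by inside/outside probes on both
sides of each candidate crossing, which makes reflection robust at concave
junctions (soma–process).  PGSE phases are accrued with the ideal
rectangular bipolar waveform discretized at dt, either from stored
trajectories or online (`simulate_pgse`), the latter holding memory constant
in the number of time steps.  Because δ/dt is not an integer, Monte Carlo
signals are compared against closed forms evaluated at the *discretized*
waveform's b-value (`discrete_bvalue`), which removes the ~0.2%
discretization offset from the oracles.

Validation oracles: mean-squared displacement = 6 D₀ t (exact in expectation
for fixed-length steps), free-diffusion signal = exp(−b D₀), uniform-ball
seeding moment E‖x‖ = 3R/4, and perpendicular-cylinder attenuation equal to
the Van Gelderen series at r = 3 µm under the protocol timings — all within
three standard errors at 10⁴ walkers.

**Glia substrates.**  Real microscopy reconstructions are replaced by a
parametric generator: a soma sphere (default 5 µm) plus 20 cylindrical
processes (radius 1–2 µm, length 30 µm) with random orientations —
isotropic by default, or Watson-distributed about the bundle axis via
``process_p2`` to mimic white-matter glia whose processes partially follow
the surrounding tract.  An SWC reader (soma sphere + one cylinder per
segment) can build substrates from real morphology files when available.

**Glia-fraction experiment.**  The axon compartment is analytic
(Watson-dispersed cylinders, p₂ = 0.7); the glia compartment is simulated;
signals are mixed per direction as (1−f_g)·axon + f_g·glia, decomposed per
shell, and both estimators applied with Dc∥ = D₀ (walkers diffuse freely
along process axes).  Standard errors come from splitting walkers into 8
groups and propagating each group's signals through the full pipeline.
Key qualitative outcomes, reproduced by the test suite:

* f_g = 0: both estimators recover the true radius (the analytic round
  trip).
* Sphere-only glia (f_g = 0.3): the SM radius is biased far more than the
  SV radius, because an isotropic compartment adds no second-order signal —
  the SV path cancels it.
* Thick-process glia: both radii are biased upward, with the SM rate at
  least the SV rate.  Getting this right required two physical choices.
  First, soma-free processes are *disjoint* compartments (walkers must not
  exchange between differently oriented processes through an artificial
  crossing hub) and axially unbounded, since a 30 µm process is axially
  restricted at 45 ms diffusion time (axial diffusion length ≈ 15 µm),
  which flattens the glia's shell ratio and buries the SV effect.  Second,
  the SV effect requires the glia's ℓ = 2 content to align with the
  bundle's: a single perfectly isotropic cell contributes only noise-level
  second-order signal, so the experiment uses processes thicker than the
  test axon (2.5–3.5 µm vs 2 µm) with mild alignment
  (``process_p2 = 0.3``), as observed for white-matter glia whose processes
  partially follow the tract.  With fully isotropic processes the SV bias
  direction is seed-dependent while the SM bias remains robustly upward —
  itself a demonstration of the SV path's relative robustness.

## Statistics

TRV = mean over pairs of √(π/2)·(2|a−b|/(a+b))·100, exactly as defined,
including the √(π/2) factor; pairs with a+b = 0 are excluded with a
warning.  CoV = 100·sd/mean with the sample (N−1) standard deviation — the
convention is a package choice and is documented here because both
conventions are in circulation.  Lin's concordance ρc uses population (N)
moments, and the accuracy coefficient is Cb = ρc/ρ (Pearson), so ρc ≤ ρ
always.  Paired comparisons are two-sided t-tests at α = 0.05 per segment
with no multiplicity correction by default; a Benjamini–Hochberg option is
available.  Segment aggregation is a NaN-aware group-by mean that reports
per-segment counts and warns on empty segments.

## Problem sizes and tolerances

The test suite and acceptance script run scaled-down but decisive problem
sizes, chosen once: 10⁴ walkers for the physics oracles (3-standard-error
checks), 4000–6000 walkers for the glia experiment, 200–400 Rician noise
repeats for recovery medians, 200 repeats for the ML-vs-LS bias comparison
at SNR 5 (where the Rician floor effect is an order of magnitude larger
than the Monte Carlo error), and 10⁴ replicates for the t-test type-I rate.
Round-trip identities are asserted at 1e-9 µm⁴ on r⁴; quadrature-based
cross-checks at 1–2%, reflecting the erf ≈ 1 and perpendicular-coupling
approximations the forward models deliberately make.

## Known limitations

* The estimators inherit every assumption of the single-compartment model;
  the package's own glia experiment shows how non-axonal processes bias
  them.
* The SV path loses validity (and SNR) as dispersion grows: SV → 0 for
  isotropic voxels, and its noise bias is noncentral-chi distributed.
* The Monte Carlo simulator has no extracellular space, no permeability,
  no surface relaxation, and parametric (not reconstructed) glia
  morphology by default.
* The Rician-ML fit requires a trustworthy σ; σ estimation is out of scope.
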