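# Methods

## The statistical model

A neutron reflectometry measurement records, per momentum-transfer bin
*i*, a neutron count N_i.  Counts are independent Poisson variables with
mean s_i r_i(ξ), where s_i is the expected number of *incident* neutrons
in the bin (flux × counting time, after slit scaling) and r_i(ξ) the
model reflectivity at the bin centre, a function of the M free sample
parameters ξ.  Reported reflectivities are N_i / s_i with uncertainty
√N_i / s_i — the square-root-of-counts rule.

Under this model the Fisher information matrix of ξ is

    g = Jᵀ M J,      J_ij = ∂r_i/∂ξ_j,      M = diag(s_i / r_i),

in nats per parameter-unit².  The Cramér–Rao bound gives parameter
uncertainties ε_j = √(g⁻¹)_jj, pairwise k-sigma confidence ellipses from
2×2 blocks of g⁻¹, and, because g is linear in the s_i and hence in the
counting time τ, the exact scaling ε ∝ τ^(−1/2) — the basis of
uncertainty projection and early-stopping decisions.  Multiple datasets
(several angles, several solvent contrasts) concatenate: parameters
shared between models appear once in ξ and their information adds.

The construction is validated internally against the exact
Kullback–Leibler divergence between the joint Poisson count
distributions at two parameter vectors,
D(ξ‖ξ′) = Σ_i [λ_i ln(λ_i/λ′_i) − λ_i + λ′_i] with λ_i = s_i r_i:
for small displacements D ≈ ½ Δᵀ g Δ.  Note that a 1σ displacement thus
corresponds to ½ nat, the second-order expansion value; the package uses
the expansion itself and does not round this to the one-nat rule of
thumb sometimes quoted.

## Forward model

Reflectivities come from the Abelès characteristic-matrix recursion for
stratified media: per-medium normal wavevectors
k_n = √((Q/2)² − 4π(ρ_n − ρ_fronting)), interfacial Fresnel coefficients
damped by the Névot–Croce factor exp(−2 k_n k_{n+1} σ²) for Gaussian
roughness of width σ, 2×2 layer matrices multiplied fronting→backing,
r = |M₁₀/M₀₀|².  Absorption (imaginary SLD), magnetism and off-specular
scattering are out of scope.  Conventions:

* a layer's `roughness` belongs to its *top* interface;
  `backing_roughness` covers the deepest interface;
* SLDs are true Å⁻² internally; configuration files use the community
  10⁻⁶ Å⁻² unit with explicit `_e-6` keys, converted at the boundary;
* below the critical edge the Névot–Croce damping of buried interfaces
  can push |r|² infinitesimally above 1; the result is clipped to [0, 1].
* a vanishing-thickness layer with *sharp* interfaces leaves r
  continuous; inserting a sharp interface above a rough one changes the
  damping bookkeeping and is a genuinely different profile.

The full model curve is `scale × smear(r) + background`.  The
background is additive detector noise and is deliberately not multiplied
by the scale factor, which normalises illumination.  A strictly positive
background is required for Fisher analyses (it keeps every Poisson rate
positive at high Q).

**Resolution smearing.**  Instrument resolution is a Gaussian dQ/Q
kernel; the stated percentage (e.g. 2.5%) is interpreted as the FWHM —
the common convention on time-of-flight reflectometers — and converted
to σ by /2.35482.  Each smeared point is the Gaussian-weighted average
of the unsmeared curve over ±3.5 kernel σ, computed by composite
Gauss–Legendre quadrature (7-point panels, 35 nodes by default,
configurable).  Against a dense (2001-node) trapezoidal convolution of
the same truncated kernel the default is accurate to ~10⁻⁴ relative on
measurement-style grids; accuracy degrades to a few ×10⁻⁴ for points
sitting exactly on a critical edge, where r(Q) has a kink.  Raising
`n_nodes` converges towards the dense reference.

## Experiment simulation

Simulation needs an incident flux table (neutrons/s per wavelength bin
at a reference angle).  Wavelengths map to Q = 4π sin θ/λ; each
wavelength's flux is assigned wholly to the geometric Q bin containing
it (histogramming of time-of-flight events — no fractional splitting).
Bin centres are the geometric mean of the bin edges.  Intensity scales
as (θ/θ_ref)², the slit-opening law for footprint-matched collimation.
Counts are drawn as N_i ~ Poisson(s_i r_i); a seed deterministically
spawns independent sub-streams per (model, condition) pair.  Bins
receiving no flux are dropped with a warning.  Multi-angle datasets are
kept per-angle; the stitched single-curve view is cosmetic and never
used for information calculations.

**Synthetic flux profile.**  Real instrument flux tables are rarely
published, so the package ships a Maxwellian moderator spectrum
φ(λ) ∝ λ⁻⁵ exp[−(λ_c/λ)²] over 1–14 Å, peak at 3 Å, integrating to
5×10⁵ neutrons/s at a 0.3° reference angle.  These defaults set the
absolute count scale of every simulation in the test suite; they are a
plausible stand-in, not a measured table, so absolute uncertainties are
illustrative while all *relative* statements (time scaling, contrast
ranking, FI-vs-posterior agreement) are flux-shape independent.  The
emulation also omits detector efficiency, gravity, polarisation and
footprint-overfill effects; passing tests therefore demonstrate the
statistical machinery, not instrument-calibrated predictions.

## Numerical choices

* **Jacobian**: central finite differences with a relative step of 0.5%
  per parameter; a parameter currently at zero falls back to an absolute
  step of 0.5% of its bound width.
* **Matrix inversion**: eigendecomposition of the diagonally
  preconditioned FI matrix (parameters span ~12 orders of magnitude
  between Å and Å⁻² units, so raw condition numbers are meaningless);
  a scaled condition number above 10¹⁰ raises an error naming the most
  degenerate parameter combination (smallest-eigenvalue eigenvector).
* **Confidence ellipses** use the marginal 2×2 block of g⁻¹, matching
  what a corner plot's 2-D marginal shows; the conditional variant
  (block of g, other parameters fixed) is available behind a flag.
* **Likelihood**: Gaussian, ½ Σ[((r_i − m_i)/δr_i)² + ln(2π δr_i²)],
  returned as a negative log-likelihood.  Zero-count points (δr = 0)
  carry no Gaussian information and are excluded from fitting and
  sampling with a logged warning.
* **Fitting**: bounded differential evolution (population-based, seeded,
  bound-respecting) followed by an L-BFGS-B refinement in
  bound-normalised coordinates with tight tolerances — the refinement is
  what brings optimiser error well below the statistical uncertainty
  scale.  Non-convergence is reported, never silently accepted.
* **MH sampler** (test oracle): random-walk Metropolis–Hastings with a
  uniform prior over the parameter bounds.  Proposal scales adapt to the
  recent chain spread during burn-in only (30% of the chain), then
  freeze, keeping the retained samples Markovian.  It exists to
  cross-check FI uncertainties, not as a production sampler.

## Bilayer model

The supported-bilayer structure is Si | SiO₂ | inner heads | tails |
outer heads | water, parameterized by area per molecule (APM): with
fixed component volumes V, each leaflet layer thickness is V/APM, so
coverage and thickness cannot drift apart.  Dry SLDs are b/V; each
layer's SLD mixes linearly towards the bulk-water SLD by its total
water fraction — defect water for tails, defect + bound water for
headgroups, a fitted hydration for SiO₂.  Bound and defect water are
summed before mixing because only the total water volume fraction
affects the SLD.  The two leaflets' tails form one merged layer by
default (`split_tails` separates them; the SLD profile is identical).

Component values default to conventional DMPC literature numbers
(headgroup 320.9 ų and 6.41×10⁻⁴ Å; tails 2×783.3 ų and
−3.08×10⁻⁴ Å per molecule; SiO₂ SLD 3.41×10⁻⁶ Å⁻²) and are fixed —
freeing them is refused, since the APM parameterization assumes known
constant molecular volumes.  They are constructor-editable for other
lipids.  Water contrasts span −0.56×10⁻⁶ Å⁻² (H₂O) to 6.35×10⁻⁶ Å⁻²
(D₂O), linearly in D₂O fraction.

Because every hydrated layer mixes with the same solvent SLD, setting
the solvent equal to a component's dry SLD makes that component's
hydration locally invisible: its FI dips to a minimum at the matched
contrast.  The contrast scan reproduces this blind spot for the SiO₂
hydration and shows that adding a second contrast never reduces the
joint information of shared parameters (FI additivity over independent
datasets).

## Design analyses

* **Time scan**: deterministic — uncertainties are recomputed from model
  reflectances at each time multiplier; no noise is drawn, because the
  τ^(−1/2) law concerns the bound itself.  A noisy-fit pathway exists
  via `estimate_fit_bias`/`fit_model` for studying estimator behaviour.
* **Contrast scan**: for each candidate solvent SLD, the joint FI of
  (already-measured contrasts + candidate) with bilayer parameters
  shared across contrasts; 100 grid points over the physical H₂O–D₂O
  range by default.
* **Fit bias**: mean(fitted) − truth over independent simulate+fit
  replicates with its standard error; >10% replicate failures aborts.
* **Dataset comparison**: counts are Anscombe transformed (2√(N+3/8),
  variance-stabilising for Poisson), per-bin paired differences form one
  observation per bin with one variate per angle, and a one-sample
  Hotelling t² tests a zero mean-difference vector against the exact F
  reference.  This reduction is sensitive to per-angle count-level
  discrepancies (the fingerprint of mis-simulated counting statistics);
  fringe-position differences cancel in the per-angle mean by design.
  Matched binning across the two experiments is required.

## Problem sizes and defaults

The standard simulated experiment is 140 points from two angles (0.7°
for 7.5 min, 2.0° for 30 min), background 10⁻⁶ (8×10⁻⁷ for the built-in
two-film reference sample), resolution 2–2.5% dQ/Q — the conditions all
examples and tests use.  The contrast-scan schedule is 15 min + 60 min
at the same angles.  Validation sizes: 200 simulation repeats for
Poisson moments, 50 trials for the comparison-test calibration, 40
simulate+fit replicates for recovery, 10⁵ MH steps for the sampler
cross-check.

## Known limitations

* Gaussian likelihood vs Poisson truth: at low counts the 1/δr² weights
  (∝ s²/N) overweight downward count fluctuations and zero-count bins
  are dropped, so fitted/posterior spreads can deviate from the FI
  prediction where information is concentrated in sparse high-Q bins.
  The FI itself matches the exact local curvature of the likelihood
  (verified against a Laplace approximation in development).
* The Cramér–Rao bound assumes an unbiased estimator; differential
  evolution can be biased for strongly correlated parameters, in which
  case FI uncertainties are a lower bound on what sampling extracts.
* Uncertainties are local (evaluated at the supplied parameter point)
  and say nothing about multimodality of the fit landscape.
* Only statistical (counting) uncertainty is modelled — no systematic
  alignment, normalisation or background-subtraction errors.
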