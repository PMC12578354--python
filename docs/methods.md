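# Methods

## Model

Cell density C(x, t) (cells/μm²; x in μm, t in hr) on a 1D transect or 2D
field of view evolves by advection-diffusion-reaction:

∂C/∂t = ∇·(D(C)∇C) − ∇·(C v_f(C) v̂) + r(C),

with polynomial density dependence

- D(C) = θ₀ + θ₁C + θ₂C²   — random motility (μm²/hr at each power of C),
- v_f(C) = θ₃ + θ₄C + θ₅C² — directed speed along the unit vector v̂
  perpendicular to the wound (μm/hr),
- r(C) = θ₆C + θ₇C²        — net proliferation (θ₆ in 1/hr).  A constant
  reaction term is excluded by construction: it would create or destroy
  cells where none exist.

With θ₆ > 0 > θ₇ the reaction is logistic, r = θ₆C(1 − C/K) with carrying
capacity K = −θ₆/θ₇, the positive root of r.  (Dimensional analysis fixes
the ratio this way round: [θ₆]/[θ₇·per-density] = cells/μm².  Some authors
print the inverse ratio for the same quantity; the number here, e.g.
0.13/92 ≈ 1.41×10⁻³ cells/μm² for a refined untreated-condition model, is
what the zero of r gives.)

## Stage 1 — weak-form regression (VSI)

Binned, smoothed density data are interpolated with P1 finite elements
whose nodes sit at the bin centres, so nodal coefficients equal measured
densities.  Testing the weak form against the same basis (Galerkin) and
integrating by parts gives, per interior node k and frame j ≥ 1, a residual
row that is linear in θ:

- target: y = −∫ (∂Cʰ/∂t) N_k dΩ, with ∂Cʰ/∂t the backward-Euler
  difference of the data between frames j−1 and j;
- columns: Ξ₀..₂ = ∫ C^p ∇N_k·∇Cʰ dΩ, Ξ₃..₅ = −∫ C^{p+1} v̂·∇N_k dΩ,
  Ξ₆..₇ = −∫ C^p N_k dΩ (p as in the ansatz).

Weighting functions vanish on the Dirichlet boundary (the whole boundary),
so boundary rows are dropped.  Replicates are aggregated by row stacking,
which is algebraically the same as minimizing the summed per-replicate
losses.  All element integrals use Gauss(-type) quadrature exact to degree
4 — one degree beyond the cubic integrands of the quadratic ansatz — so
quadrature error plays no role in inference comparisons.

Two choices matter on counting data:

- **Operator evaluation at the time-centred field** (Cʰ_j + Cʰ_{j−1})/2.
  This matches the backward difference to second order, and it makes the
  observation noise entering the operator columns uncorrelated with the
  differencing noise entering the target.  Evaluating at frame j instead
  shares the frame-j noise between the two sides, an errors-in-variables
  covariance that systematically misorients the reaction pair (measured on
  synthetic data: the fitted logistic branch flips sign on every seed).
- **One backward difference per temporal smoothing window** (the
  `library_stride` default).  Differences taken finer than the filter
  support compare two nearly identical filtered frames, so their rows are
  dominated by cancellation noise; striding by the window length makes
  consecutive rows carry independent noise at the largest per-row signal
  the filter allows.  Unsmoothed data use every frame.

### Stepwise elimination and model selection

From the full 8-term library, the term whose exclusion grows the loss least
is removed, down to one term.  Exclusions whose losses differ by less than
the statistical resolution of the loss (2/n_rows relative, the O(loss/n)
fluctuation of exchanging one noise-level column for another) are treated
as tied, and the tie is broken by dropping the higher-order density
dependence — noise cannot tell the three diffusivity variants apart, and
the simpler dependence is preferred.

Two stopping rules are provided.  `select_model` implements the loss-elbow
reading: the smallest active set whose loss is within (1+ρ) of the
full-library loss (ρ defaults to 0.05; an absolute floor of 10⁻¹²·|y|²
keeps the comparison meaningful when noise-free losses sit at machine
precision).  `select_significant` (the pipeline default) implements the
classical F-to-remove rule: eliminations are accepted while their loss
growth is statistically indistinguishable from removing a pure-noise column
(χ²₁ at 95%).  The elbow rule presumes the loss is signal-dominated; on
counting data the full-library loss is mostly observation noise (the entire
explainable signal can be a percent of |y|²), and only the significance
rule remains discriminating there.  Both agree on noise-free data.

### The transport guard

The weak-form loss is often nearly flat in the diffusion coefficients —
random motility is the least identifiable mechanism in this data, and its
regression estimate is strongly attenuated by noise — so selection can
drop every diffusion column while a pure-reaction PDE is structurally
incapable of wound closure (r(0) = 0 keeps the scratch centre empty).  The
pipeline therefore expands a diffusion-free selection with the constant
diffusivity term and re-fits the expanded set by least squares before
refinement (`ensure_transport=True`, overridable).  This mirrors the
established workflow of expanding a model when the misfit shows low
sensitivity to diffusive coefficients; beyond this guard, model expansion
is left to the user, with gradient magnitudes reported to inform it.

## Stage 2 — PDE-constrained refinement

ℓ(θ) = ‖C′ʰ(θ) − Cʰ‖²_{L²(Ω×[0,T])} is minimized over the active
coefficients, where C′ʰ solves the ADR equation from the data's first frame
with Dirichlet values taken from the (smoothed) data trace at the boundary
(interpolated linearly across solver substeps).  Space uses the consistent
mass-matrix norm (exact for P1 fields); time uses the trapezoid rule over
data frames — the lowest-order consistent choice.

The forward solver is backward Euler with Newton iterations (analytic
Jacobian from the polynomial ansatz; consistent, non-lumped mass matrix;
absolute/relative stopping tolerances 1e-8/1e-9; previous step as initial
guess).  Negative intermediate densities are reported, never clipped, so
the adjoint stays consistent with the computed trajectory.

Gradients come from the **discrete adjoint** of this exact scheme — a
terminal-to-initial sweep through the stored step states solving Jᵀλ
systems with the same Jacobians — rather than a discretized continuous
adjoint, so they match the discrete loss to solver precision (verified
against central finite differences to better than 1e-9 relative in the
test suite; the acceptance tolerance is 1e-5).  Because the per-step
operator is linear in θ, ∂F/∂θ_m is the m-th weak-form operator column.

Optimization is L-BFGS-B with tolerance 1e-9, bounds θ₀, θ₁, θ₂ ≥ 0 when
active (positive diffusivity), initialized at the regression estimates and
run in per-component scaled variables x = θ/|θ_init| — coefficients span
three or more orders of magnitude and raw-unit quasi-Newton stalls along
the flat directions.  Initial points are projected into the bound-feasible
box (as the optimizer itself would).  A line-search trial that drives the
forward solve to divergence returns an infinite loss, so the search
backtracks.  After convergence, D(C) is checked for positivity over the
observed density range and flagged if violated.

## Uncertainty

- **Contour scans**: the misfit on a grid in two coefficients (default
  ±50%, 41×41), others fixed at the optimum; normalized by the grid
  minimum, with forward failures recorded as missing points.  Broad valleys
  mark poorly constrained directions — in practice a shallow minimum along
  diffusivity, and an affine trade-off between the linear and quadratic
  reaction coefficients whose sharp direction is the carrying capacity.
- **Laplace summary**: a local Gaussian approximation to the posterior,
  covariance 2σ̂²H⁻¹ with H the finite-difference Hessian of the misfit at
  the optimum (central differences of the adjoint gradient when available)
  and σ̂² = final misfit / residual degrees of freedom — the classical
  nonlinear-least-squares convention, stated in output metadata.  Degrees
  of freedom count one independent frame per temporal smoothing window,
  since the filter correlates frames within a window.  A non-positive-
  definite Hessian falls back to a pseudo-inverse with the flat directions
  reported.  Finite-difference steps at zero-valued coefficients borrow the
  largest active magnitude, since a relative step at zero would vanish.
- **Carrying capacity**: K = −θ₆/θ₇, defined only for θ₆ > 0 > θ₇.

## Synthetic data generator

The generator emulates the observation process of a nuclear-marker scratch
assay and defines the package's study conditions: a 2 mm 1D transect (2D
optional) with a 400 μm scratch (smoothstep edges over 50 μm, half-plateau
crossings exactly at the nominal edges), far-field plateau 10⁻³ cells/μm²
**at the carrying capacity** — the monolayer is grown to confluency before
scratching, so the far field is growth-saturated — truth model
θ₀ = 30 μm²/hr, θ₆ = 0.05 /hr, θ₇ = −50 (K = 10⁻³), frames every 20 min
over 48 h (the live-imaging cadence; a 12-h/six-seeding-density classic
design is provided as `jin_like_profile_set`), 100 μm bins with a 100 μm
strip width (≈10 cells per occupied bin), and four replicate wells,
aggregated only in the inference losses.  The truth trajectory is
integrated with zero-flux boundaries (cells do not leave the field of
view) at 10-min implicit steps; observed counts per bin and frame are
Poisson with mean C × bin area, with centroids placed uniformly in their
bin.  An additive-Gaussian noise mode exists for filter-tuning studies.
Small negative P1 undershoots near the sharp scratch edges are clipped by
the observation map (Poisson intensities are nonnegative); the nodal truth
series is kept unclipped.

What the generator does **not** emulate: cell-cell exclusion or finite
cell size, segmentation errors and over/under-counting in dense regions,
drift or illumination artifacts, densities above carrying capacity
(real assays overshoot and show crowding-induced death; a logistic truth
approached from below never exceeds K), and history-dependent (delayed)
responses.  Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated counting-noise regime, not
robustness to every artifact of real microscopy.

## Smoothing conventions

Moving-average windows are separable and centred: each spatial axis first,
then time (order recorded in metadata).  A window of physical width w on
spacing h covers the 2⌊w/2h⌋+1 samples whose centres lie within w/2 — the
discrete window never exceeds the physical one, so a 150 μm window is a
3-bin average on 50 μm bins and the identity on 100 μm bins (a warning is
emitted).  At the data boundary the window shrinks to the available
samples rather than fabricating data outside the observed domain.
Smoothed values are clipped at zero.  Over-smoothing is the main bias risk
of the whole pipeline: a window dilated beyond its physical width flattens
the moving front, and fitting the un-smoothed PDE to over-smoothed fronts
inflates diffusivity and deflates the reaction coefficients.

## Numerical sizes used in the verification suite

The acceptance checks run at desk scale: 42-element 1D meshes (the
reference 1D configuration; 2D uses a structured triangulation with the
lower-left-to-upper-right diagonal, density configurable), 48-h horizons,
10–20 noise seeds for the recovery and calibration studies, and forward
solves at the data cadence (20-min implicit steps; 8 substeps per frame
for the noise-free closure fixture).  These sizes were chosen so the whole
suite verifies every stage in a few minutes on one CPU.

## Known limitations

- VSI coefficient estimates on counting data are attenuated (diffusivity
  most strongly; the untreated-condition pattern of a ~4× VSI-to-refined
  diffusivity gap is reproduced on synthetic data); they are structure
  finders and refinement initializers, not final estimates.
- The Laplace covariance quantifies curvature of the misfit only.  It does
  not propagate the noise in the initial condition and boundary trace,
  which the refinement trajectory inherits; empirically the reaction-pair
  standard deviations are under-dispersed by roughly 2× at the default
  conditions (the 3-sd scatter-coverage check sits near its 90% margin),
  while the diffusivity standard deviation is well calibrated.  The
  refined growth rate also carries a small (~+4%) bias from temporal
  smoothing of the fast early trough regrowth.
- Stabilized schemes for advection-dominated regimes are not implemented;
  inferred models in this data family are diffusion/reaction only.
- No L1/ridge regularization paths and no operator discovery beyond the
  8-term library; no delayed (history-dependent) models.
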