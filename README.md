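# scratchpde

Inference of advection-diffusion-reaction (ADR) models of collective cell
migration from scratch-assay (wound-healing) density data, in two stages:

1. **Variational system identification (VSI).**  The cell density field
   C(x, t) (cells/μm², binned from nuclear centroids) is interpolated with
   piecewise-linear finite elements, and the weak (variational) form of

   ∂C/∂t = ∇·(D(C)∇C) − ∇·(C v_f(C) v̂) + r(C)

   is tested against the same basis.  With the polynomial ansatz
   D(C) = θ₀ + θ₁C + θ₂C², v_f(C) = θ₃ + θ₄C + θ₅C², r(C) = θ₆C + θ₇C²,
   the residual is linear in θ: a regression y = Ξ·θ whose target carries the
   backward-Euler time derivative of the data and whose eight columns carry
   the weak-form operator integrals.  Greedy backward elimination
   (stepwise regression) then produces a parsimony path, and a stopping rule
   selects the model size.  Because the weak form moves one derivative onto
   the weighting functions, no second derivatives of noisy data are ever
   taken.

2. **PDE-constrained refinement.**  The surviving coefficients are refined
   by minimizing the space-time L² misfit between the implicit (backward-
   Euler/Newton) forward solution and the data field, with discrete-adjoint
   gradients and bound-constrained quasi-Newton (L-BFGS-B; diffusivities are
   kept nonnegative).  VSI coefficient estimates are attenuated by
   observation noise — diffusivity especially — and refinement against the
   full trajectory removes that attenuation.

The package is for quantitative biologists and modelers who want to turn
scratch-assay movies into interpretable mechanism parameters — random
motility D, directed motion v_f, proliferation rate and carrying capacity —
and to compare them across perturbations (drug doses, cell lines).  A
synthetic scratch-assay generator with known ground truth (Poisson counting
noise on forward-simulated density fields) makes every stage verifiable by
parameter recovery, with no external data.

## Worked example

Generate a synthetic assay (2 mm field, 400 μm scratch, plateau density
10⁻³ cells/μm² at carrying capacity, four replicate wells imaged every
20 min for 48 h, Poisson counting noise at ~10 cells per 100 μm bin), run
the full pipeline, and compare with the generating truth:

```sh
cat > run.yaml <<EOF
synthetic:
  seed: 7
refine:
  nsub: 1
out: refined.json
EOF
scratchpde pipeline --config run.yaml
```

which prints (θ ordering: D:1, D:C, D:C², v:1, v:C, v:C², r:C, r:C²):

```
VSI selected terms (0, 6, 7) (expanded with constant diffusivity)
VSI theta     = [ 16.851692   0.         0.         0.         0.         0.
   0.032509 -32.239282]
refined theta = [ 35.669696   0.         0.         0.         0.         0.
   0.049427 -49.3393  ]
truth theta   = [ 30.     0.     0.     0.     0.     0.     0.05 -50.  ]
```

Reading the numbers: stepwise elimination discards all three advection
terms and the density-dependent diffusivities, keeping the reaction-
diffusion structure {D:1, r:C, r:C²}.  The regression estimates
(D ≈ 17 μm²/hr, growth 0.033 /hr) are attenuated by counting noise;
PDE-constrained refinement recovers D ≈ 36 μm²/hr, growth 0.049 /hr and
saturation −49 μm²·cell⁻¹·hr⁻¹ against the truth (30, 0.05, −50).  The
implied carrying capacity −θ₆/θ₇ ≈ 1.0×10⁻³ cells/μm² is recovered to ~0.2%
— the reaction zero-crossing is pinned far more sharply by the data than
the growth rate or diffusivity individually.

The same stages are available as individual commands on real centroid
tables (`scratchpde ingest`, `closure`, `vsi`, `simulate`, `refine`,
`uncertainty`, `synth`) and as library functions
(`scratchpde.pipeline.infer_model` et al.).

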