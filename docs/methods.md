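# Methods

`atlasguide` estimates a dense deformation between a fixed CT-like head
volume and a moving MR-like atlas template, and uses it to propagate the
atlas's anatomical labels into the CT frame. This note records the model,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Registration model

The deformation is parameterized by an Eulerian displacement field
`u` on the fixed image's voxel grid, `y(x) = x + u(x)`, with pull-back
warping `T(y)(x) = T(x + u(x))`. The field minimizes

```
J(u) = NGF(R, T(y))
     + α/2 Σ_k ‖Δy_k‖²                      (curvature)
     + β ∫ ψ(det ∇y)                        (volume change / fold barrier)
     + γ/2 ( ‖M_BP^T(y) − M_BP^R‖² + ‖M_V^T(y) − M_V^R‖² )   (masks)
     + δ/2 Σ_ℓ ‖y(r_ℓ) − t_ℓ‖²              (landmarks)
```

* **NGF similarity.** Normalized gradient fields compare local gradient
  *directions*, which is what makes CT–MR registration possible without a
  learned or statistical intensity model. The edge parameters `ε_R, ε_T`
  damp gradients at the noise level; with the augmented inner product
  `⟨a,b⟩_ε = a·b + ε` and norm `‖a‖_ε = √(a·a + ε²)` the per-voxel
  integrand `1 − (⟨∇R,∇T⟩_{ε_Rε_T} / (‖∇T‖_{ε_T}‖∇R‖_{ε_R}))²` lies in
  [0, 1] (Cauchy–Schwarz on the ε-augmented vectors), so the distance is
  bounded by half the domain volume.
* **Curvature.** Squared Laplacian of each displacement component. Since
  `Δ(identity) = 0`, affine deformations are not penalized.
* **Volume penalty.** `ψ(t) = (t−1)²/t` for `t > 0`, `+∞` otherwise.
  `ψ(t) = ψ(1/t)` penalizes growth and shrinkage symmetrically, and the
  infinite barrier at `t ≤ 0` forbids folds: combined with a monotone line
  search, no accepted iterate can change topology.
* **Guidance.** Binary masks of brain parenchyma (BP) and the ventricle
  union V = LLV ∪ RLV ∪ FV enter a soft L² overlap penalty; the warped
  moving mask is *linearly* interpolated and never re-thresholded during
  optimization, otherwise the term would be piecewise constant with zero
  gradient. Ventricle centers of gravity give point correspondences
  `(r_ℓ, t_ℓ)`; a COG may legitimately lie outside its (concave) structure —
  it is a reference point, not an anatomical landmark. Structures that are
  empty on either side are dropped from the γ/δ terms with a warning so
  pathology and coarse pyramid levels degrade gracefully.

All integrals use midpoint quadrature over every voxel (weight = voxel
volume in mm³), including boundary voxels.

## Discretization and derivatives

* First derivatives (image gradients and `∇u` for the Jacobian): central
  differences in the interior, one-sided differences on boundary slices —
  exact for affine fields on the entire grid. Degenerate (length-1) axes
  contribute zero.
* Curvature Laplacian: 7-point stencil with replicate-edge (zero-Neumann)
  boundaries. This operator is symmetric, so the curvature gradient is
  simply `vol·L(L u_k)`.
* Interpolation: trilinear for intensities and soft masks, nearest-neighbor
  for labels and binary masks. Out-of-extent samples take the value 0
  (background). The analytic derivative of the trilinear interpolant with
  respect to the sample position is used in the chain rule for the NGF and
  mask terms, so all five term gradients are exact for the discrete
  objective (they pass central-difference checks at ~1e-10 relative error;
  note the discrete objective is only piecewise smooth across trilinear
  cell faces, so difference quotients need steps ≲1e-6 voxel).
* Sample positions within 1e-9 voxel of a lattice point are snapped onto
  it, making the zero-displacement warp bit-exact despite world↔index
  round-off.

## Optimization

Multi-level coarse-to-fine over a factor-2 pyramid (default 3 levels):
intensities are mean-pooled, masks mean-pooled then thresholded at 0.5,
ventricle COGs recomputed per level from the pooled masks, and the
displacement (stored in mm, hence resolution-independent) prolonged to the
next level by trilinear interpolation.

Each level runs a limited-memory BFGS (two-loop recursion, memory 10) with
Armijo backtracking (c = 1e-4, halving, ≤ 25 halvings; the first step is
capped at one voxel of displacement change). Steps with infinite objective
(folds) are rejected outright by the line search, which both realizes the
ψ barrier and makes the per-level objective trace non-increasing by
construction. A level stops when the gradient max-norm falls below 1e-3 of
its initial value, the iteration cap is reached, or the line search fails
(the best iterate is returned with a warning). The optimizer is fully
deterministic; the config seed exists only for downstream stochastic
tie-breaking and experiment plumbing.

Initialization translates the moving BP centroid onto the fixed BP centroid
(optionally with an isotropic scale from the BP volumes, off by default);
with empty BP masks it falls back to zero with a warning.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| α (curvature) | 40 | mm⁴·intensity⁻¹-ish (weight) | tuned on the phantom suite: strong smoothing lets boundary/guidance information interpolate through homogeneous parenchyma; smaller values leave the interior under-determined |
| β (volume) | 0.1 | weight | mild symmetric volume control; the barrier does the topological work |
| γ (masks) | 10 | weight | dominates where masks disagree; drives the ventricle alignment the pipeline is built around |
| δ (landmarks) | 5 | weight | long-range pull when masks do not yet overlap; near-neutral once they do |
| ε_R, ε_T | auto | intensity/mm | 0.1 × mean gradient magnitude per image per level; the fraction is a declared repository convention |
| levels | 3 | — | 48³ → 24³ → 12³; the coarsest level still resolves the lateral ventricles |
| iterations/level | 100 | — | cap; levels usually stop earlier on the gradient test |

Weights are deliberately exposed as configuration: they are repository
defaults tuned on the synthetic phantom suite, not constants of the method.

## Synthetic phantoms

The generator rasterizes an ellipsoidal brain (default semi-axes
19 × 21 × 17 mm in a 48³, 1 mm grid) with a mirrored pair of lateral
ventricles, a small fourth ventricle, a 2.5 mm bright "skull" shell, and
eight parenchyma parcels that stand in for the gray/white and deep-nuclei
structure of a real anatomical atlas. The same geometry is rendered twice:
CT-like (bright shell, mid parenchyma, dark ventricles) and MR-like
(dark shell, bright CSF, distinct parcel contrast) with additive Gaussian
noise (σ = 0.02 on a 0–1 intensity scale). Labels are
{0 background, 1 parenchyma, 2 LLV, 3 RLV, 4 FV, 5–12 parcels}; guidance
masks are exactly consistent with the labels, with BP = all labelled tissue.

Ground-truth deformations are periodic-stationary Gaussian-smoothed white
noise rescaled so the largest displacement equals the requested amplitude,
rejection-resampled until `min det ∇y > 0.2` so recovery problems stay well
posed under the barrier. Periodic smoothing is used deliberately: edge-
replicating smoothing inflates boundary variance and the max-rescaling
would then be dominated by corner artifacts, leaving almost no displacement
inside the brain.

Inter-subject variability (for ablation and multi-atlas experiments) is
drawn by `random_subject_spec`: brain semi-axes jitter ±1.5 mm, a shared
lateral-ventricle scale factor in [0.85, 1.45] (ventricular enlargement is
the clinically common direction), independent position jitter per
structure, and broken mirror symmetry.

**What the phantoms do not emulate:** Hounsfield calibration, bone/beam
artifacts, partial-volume effects at real cortical detail (sulci, fissures
— the main source of the large Hausdorff values real cohorts show),
pathology such as hemorrhage, and segmentation errors in the guidance
masks (phantom masks are exact). Passing the phantom experiments therefore
demonstrates the correctness and the qualitative behavior of the machinery
(guidance helps; selection never hurts), not clinical-grade accuracy.

## Experiment design and problem sizes

All experiments run on 48³ phantoms at 1 mm spacing with per-level
iteration caps (coarse→fine) of (100, 50, 25) or (150, 80, 40) for the
recovery study; these sizes were fixed once as the package's desk-scale
study conditions.

* **Identity recovery**: registering a phantom to itself must return
  essentially zero displacement (the objective gradient vanishes at the
  global minimum).
* **Deformation recovery**: same-anatomy pairs deformed by known smooth
  fields (amplitude 4 mm, smoothness 20 mm). Endpoint error is evaluated
  over the brain-parenchyma mask — outside the head nothing constrains the
  field and errors there are irreducible by design. Large ground-truth
  smoothness is chosen deliberately: tangential motion along structure
  boundaries is invisible to both edges and masks, so only the smooth,
  data-determined component of a field is recoverable; a rougher ground
  truth would measure the prior mismatch, not the machinery.
* **Guidance ablation**: different-anatomy subjects (see above) deformed
  on top, registered to a fixed atlas under none / masks / masks+landmarks
  guidance; compared by warped ventricle-union Dice.
* **Multi-atlas / bootstrap**: a pool of subjects is bootstrapped against
  the MR atlas (promotion threshold Dice ≥ 0.94, k = 3 — promoting the
  smallest useful number keeps bootstrapped-label risk low); selection by
  global ventricle Dice with first-index tie-break. Because the MR-atlas
  candidate is itself in the candidate list, multi-atlas selection can by
  construction never score below the single-atlas result.

## Known limitations

* Axis-aligned grids only; oblique NIfTI affines are rejected, not
  resampled.
* The displacement parameterization is dense and Eulerian; no
  diffeomorphic/stationary-velocity option, and the inverse field is not
  computed.
* The γ term assumes reasonable pre-alignment (it acts only where warped
  and fixed masks interact); grossly failed initialization is not recovered.
* Edge-parameter estimation is a global heuristic; strongly non-stationary
  noise would need per-region ε.
* `ψ` bounds volume change softly; it does not enforce a hard Jacobian
  floor, only positivity.
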