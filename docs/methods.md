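# Methods

This note records the model as implemented, the discretization and
numerical choices, the defaults and the reasoning behind decisions that
were genuinely open, and what the synthetic fixtures do and do not probe.

## Model

Two closed, oriented hypersurfaces `M₁, M₂ ⊂ (0,1)ⁿ` (n = 2, 3) are given
as zero level sets of their signed distance functions `d₁, d₂` (negative
inside; `|∇d_i| = 1` away from the skeleton). A deformation
`φ : [0,1]ⁿ → ℝⁿ` is sought minimizing

    E_ν[φ] = E_match + E_mem + E_bend + E_vol.

All surface terms are narrow-band volume integrals weighted by `η_σ(d₁)`,
a C∞ bump `c(σ)·exp(−1/(1−(t/σ)²))` supported on `[−σ, σ]` and normalized
to unit integral, so the *strength* of the surface terms is independent of
the band width. Writing `n_i = ∇d_i`, `P_i = 1 − n_i⊗n_i`, `S_i = D²d_i`:

* **Matching.** `(1/ν)∫ η_σ(d₁)|d₂∘φ − d₁|²`. A penalty, not a
  constraint; each offset `{d₁ = c}` inside the band is pulled onto
  `{d₂ = c}` as ν → 0.
* **Membrane.** `δ∫ η_σ(d₁) W(D_tgφ + (n₂∘φ)⊗n₁)` with
  `D_tgφ = (P₂∘φ)·Dφ·P₁`. The rank-one completion `(n₂∘φ)⊗n₁` realizes a
  Kirchhoff–Love normal-transport assumption and makes the argument an
  n×n matrix whose determinant/Frobenius norm are the tangential area and
  length distortions. The projection onto the *target's* tangent plane
  (`P₂`) is what makes the integrand polyconvex in the relevant sense;
  dropping it (ablation flag `ablate_P2_in_membrane`) yields a density
  that is not rank-one convex and produces oscillatory almost-minimizers
  under compression.
* **Bending.** `δ³∫ η_σ(d₁) W(Λ(C₁, C₂∘φ, Dφ))`, where
  `C_i = 𝒞(P_i S_i P_i + n_i⊗n_i)` are SPD classifications of the
  extended shape operators, and
  `Λ[M,N,A] = P₂N^½P₂ A P₁M^{−½}P₁ + n₂⊗n₁`. Λ is orthogonal iff
  `AᵀP₂NP₂A = P₁MP₁`, so `W(Λ)` penalizes curvature mismatch while
  remaining weakly lower semicontinuous. The naive quadratic penalty
  `δ³∫η_σ|Dφᵀ(S₂∘φ)Dφ − S₁|²` is available for comparison
  (`use_naive_bending`). Note the model compares the curvature of the
  *target's* level sets at the deformed position with the reference ones;
  it deliberately does not see the curvature of the deformed image φ(M₁).
* **Volume.** Default: `c_vol ∫ W(Dφ)` with the same density W (finite at
  degenerate determinants, convenient under a free boundary). Optional:
  `∫ α|Dφ|^p + β|Cof Dφ|^q + γ(det Dφ)^{−s}` with +∞ when det ≤ 0,
  exponents `p,q > n`, `s > (n−1)q/(q−n)`, and coefficients satisfying the
  stationarity condition `(n+1)·n^{(n−1)/2}(α + (n−1)β) = n²γ` so that
  rotations are critical points. Built-in calibrations:
  n = 3: (p,q,s) = (4,4,9), α=β=1, γ=4; n = 2: (3,3,4), α=β=2, γ=3√2.

**Density.** `W(A) = μ/2|A|² + λ/4(det A)² + (μ+λ/2)e^{−(det A−1)} −
(n+2)μ/2 − 3λ/4` vanishes on SO(n), is finite as det A → 0 (required,
since the extended tangential derivative can legitimately degenerate when
the configuration is poor), and its Hessian at the identity is twice the
Lamé–Navier form `μ|sym H|² + (λ/2)(tr H)²`. Defaults λ = μ = 1.

**Classifier.** Truncated absolute value by default:
eigenvalues mapped through `max(|λ|, τ)`, eigenvectors kept, τ = 1 (a mild
floor on the unit domain). It represents the matching objective faithfully
where principal curvatures share signs and exceed τ; a saddle can be
mistaken for an elliptic point of equal |curvature| — accepted, globally
compensated in practice. The eigenvalue-shift variant `B + μ̄·1` is
implemented but requires the caller to supply μ̄ (a strict bound on the
most negative principal curvature); no universal default is meaningful, so
none is given.

## Discretization

* **Grids.** Adaptive quadtrees/octrees over `[0,1]ⁿ`; cells keyed by
  (level ℓ, integer anchor), h = 2^{−ℓ}, identified by their minimal
  corner; half-open cells with the upper domain boundary closed fix facet
  ownership. Refinement around both surfaces (width 3h at the target
  level, conservative half-diagonal margin using the 1-Lipschitz property
  of distances) is monotone; balance is enforced over facet *and*
  edge/corner adjacency — slightly stronger than facet-only 2:1, so every
  hanging node is exactly an edge midpoint (weights ½,½) or 3D face
  centre (¼×4) of one coarser neighbour, and constraint chains resolve
  recursively in one sweep. DOF indices are assigned in sorted key order:
  re-indexing an identical grid is bitwise reproducible.
* **Fields.** Continuous piecewise multilinear; hanging values eliminated
  through a sparse constraint matrix. Point location descends
  finest-level-first through per-level sorted key tables (vectorized).
  Energy assembly precomputes sparse evaluation/gradient operators at all
  quadrature points, so an energy or gradient evaluation is a handful of
  sparse matvecs plus batched small-matrix algebra.
* **Quadrature.** Tensor-product 2-point Gauss per leaf. Band terms only
  visit leaves meeting `{|d₁| ≤ σ}` (corner test with Lipschitz margin);
  `η_σ` is evaluated pointwise, with no cut-cell splitting — justified by
  tying σ = 2h to the mesh. Quadrature points where `η_σ(d₁)` underflows
  to exactly zero are dropped (they would otherwise produce 0·∞ against
  overflowed densities at folded trial steps; the density's exponential
  is additionally capped at e⁵⁰⁰).
* **Signed distances.** Exact point-to-segment/point-to-triangle values
  on all nodes of surface-adjacent cells (plus one ring), then first-order
  upwind fast marching over DOF nodes in min-heap order. The upwind
  stencil uses same-level cartesian neighbours (the adaptive grid is a
  subgrid of the uniform finest grid) and falls back to the available
  coarser neighbour across level jumps; hanging nodes never propagate.
  Signs are a separate pass: polygon containment (even–odd) in 2D,
  ray-parity with deterministically seeded perturbation retries in 3D;
  input orientation is honoured (reversing it flips the sign field).
  Triangle distances are prefiltered by a KD-tree on centroids with a
  certificate radius; points without a certificate fall back to the
  exhaustive scan (cell-selection queries skip the fallback — they only
  need distances up to one triangle radius).
* **Geometry coefficients.** Normals: lumped-mass L² projection of the FE
  gradient, then normalization (lumped keeps the operation local and
  monotone; nodes on the skeleton are flagged and given an arbitrary unit
  direction — they never carry band weight). Shape operators: Hessians of
  moving least-squares quadratic fits over the r nearest DOFs (r = 12 in
  2D, 30 in 3D; scaled normal equations, one enlargement to 2r on
  rank-deficiency, then error). Classified operators and their roots are
  computed at nodes; compositions at deformed points interpolate nodal
  matrices, re-symmetrize and re-classify (re-clamping after
  interpolation keeps them SPD), and interpolated normals are
  re-normalized.
* **Gradient.** The discrete energy's first variation is assembled exactly
  through the chain rule: the A-dependence (through Dφ) of every density
  is closed-form (for bending, Λ is *linear* in A once the matrix roots
  at the base point are fixed); the y-dependence (through the
  interpolated target coefficients d₂, n₂, C₂ at φ(x)) uses per-point
  central differences (ε = 1e-6) of the same code path the energy runs,
  then sparse-matrix assembly. Off-domain positions are clamped
  componentwise; clamped coordinates get zero gradient (sub-gradient
  choice). The pointwise difference quotients are the only inexactness
  (near machine precision off the interpolation kinks); the global
  central-difference check passes at 1e-4 relative even where the τ-clamp
  is active.

## Optimization

Fletcher–Reeves nonlinear CG in the lumped-L² inner product with Armijo
backtracking (slope 1e-4, backtracking ½, persistent step with mild
regrowth, minimum step 1e-12), restart to steepest descent every 50
iterations or on a non-descent direction; infinite/huge trial energies are
rejected by the line search. Defaults: 500 iterations per level, gradient
tolerance 1e-6. The cascadic loop starts from the identity on the coarsest
grid, and per level refines the grid around both surfaces, recomputes
distances and geometry, sets σ = 2·2^{−ℓ}, divides ν by 10, halves c_vol,
prolongates the deformation by point evaluation, and minimizes again. A
stalled level proceeds with a flag (no V-cycles, no coarsening). Boundary
conditions are free (Neumann) by default; a Dirichlet option pins boundary
DOFs to the identity. There is no randomness anywhere: runs are bitwise
reproducible.

## Synthetic fixtures and what they show

The analytic fixtures (circle, ellipse, rounded rectangle, sphere,
ellipsoid) have exact signed distances (conic foot points by bisection
+ Newton on the standard scalar equation), so discretization errors can be
measured directly: band distance errors ≤ 2h at the working levels,
shape-operator eigenvalues within O(h) of {1/ρ, 0} / {1/ρ, 1/ρ, 0}.

The oscillation curves are unit-speed closed curves whose tangent is
`R sin(kξ)·e_r(ξ) + √(1−R²sin²kξ)·e_θ(ξ)` in the polar frame of the source
circle parametrization; for integer k ≥ 2 they close *exactly* (the radial
term has zero average, the tangential speed carries only harmonics of
order 2k) and converge in Hausdorff distance, but not in tangent
direction, to the circle of radius `r₀ = (2/π)E(R)` (complete elliptic
integral of the second kind). The band test integrates the naive membrane
energy analytically in polar coordinates over offsets of the curve; the
band width is kept a safe fraction of the curve's reach `≈ 1/(1+Rk)`
(beyond it the offset extension self-intersects and the construction is
meaningless). In that regime the oscillation maps carry ≪ the energy of
their weak limit — the lower-semicontinuity failure at finite, checkable
size. The rank-one probe evaluates the naive density on
`B(λ) = [[λ,0],[1−λ,0]]` through the general trace/determinant route,
giving 0 at the endpoints and ½ at the midpoint.

The compression ablation (large ellipse onto a clearly smaller circle,
perimeter ratio ≈ 1.4) shows the mechanism operationally: the full model
compresses the band smoothly (tangential stretch uniformly below one),
the P₂-less membrane clings to tangential isometry by oscillating
(an order of magnitude more sign changes of stretch−1 along the band).
The compression ratio matters: near ratio 2 a double covering of the
target becomes tangentially cheap and even the full model can reach an
orientation-preserving wrapped local minimum — the simplified volume term
carries no global injectivity barrier. This is a known limitation, shared
with any penalty-based level-set formulation without the +∞ determinant
barrier.

What the fixtures do *not* probe: real segmentation noise, thin/creased
geometries near the classifier floor τ, topology mismatches (the method
assumes diffeomorphic shapes), and large rigid misalignments — a rotation
of π/6 about the domain centre is recovered on the band to sub-mesh
accuracy, while a rotation of π is out of reach of the first-order descent
from an identity start and is not claimed.

## Problem sizes

The default test and demonstration runs use 2D grids at levels 4–7
(finest h = 2⁻⁷, a few thousand DOFs) and 3D grids at levels 5–6 for the
distance/curvature studies (tens of thousands of DOFs) — sizes chosen so
the full suite and the probe scripts complete in minutes on one core
while every asymptotic claim is measured at at least two resolutions.
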