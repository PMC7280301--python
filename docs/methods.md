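# Methods

This note documents the models, numerical choices and known limitations of
`vesselvfm`, a pipeline for regional inverse material characterization of
thick-walled, dissected vessel segments from fused surface and volumetric
displacement measurements.

## Problem setting

A dissected murine suprarenal aorta, mounted at its in vivo axial stretch
λ^iv, is pressurized quasi-statically (7 pressures, 20–140 mmHg, at three
axial stretches 0.95/1.00/1.05 × λ^iv — 21 load states). Displacements are
measured on the adventitial surface (a panoramic-DIC-style angular × axial
grid, 3 components) and inside the wall (a DVC-style 3D lattice carrying
only in-plane components; the axial voxel size makes the axial component
unreliable). The reference configuration is the (80 mmHg, λ^iv) state. The
goal is a sector-wise map of the parameters of a four-fiber-family +
thrombus hyperelastic model, identified with the virtual fields method
(VFM), plus derived maps of circumferential stretch, circumferential Cauchy
stress, linearized circumferential stiffness and stored energy density.

## Geometry and local basis

The domain Ω between the luminal surface S_in and the adventitial surface
S_out is a tetrahedral mesh with per-element region labels (wall or
intramural thrombus). The vessel axis is the global z-axis; Θ = atan2(y, x).
A transmural scalar ξ solves Laplace's equation (linear tetrahedral FE,
ξ = 0 on S_in, ξ = 1 on S_out; Dirichlet rows eliminated; sparse direct
solve, residual checked against 1e-10 relative). Per element, the radial
direction e_o is ∇ξ orthogonalized against the axial direction e_a and
normalized (the orthogonalization is required for the fiber geometry to be
well-posed); e_c = e_a × e_o completes a right-handed orthonormal triad.
Material sectors are an N_Θ × N_Z partition of Ω; tets are binned by
centroid with half-open angular bins wrapping at ±π.

Axis-constrained co-registration of two point clouds (rotation about and
translation along the axis) minimizes a symmetric nearest-neighbour sum of
squared distances, with a coarse 1° rotation scan before Nelder–Mead
refinement to avoid the cost's local minima.

## Displacement fusion

Transverse displacement components are assumed to vary linearly in R
between fitted inner-surface nodal values and the measured outer values,
blended across the surface grid by periodic bilinear shape functions ζ.
The inner nodal values solve a sparse linear least-squares problem against
the valid volumetric samples; the solve is formulated in the offset
(u_in − u_out) with a small ridge (1e-6 × the largest normal-matrix
diagonal), so grid nodes without volumetric support (imaging shadows)
default to the outer value, i.e. uniform through-wall motion. The axial
component follows a Love–Kirchhoff cross-section field
w = w_av(Z) + R_x(Z) X + R_y(Z) Y fitted per axial station to the surface
data; stations with fewer than three usable nodes inherit the nearest
neighbour.

Displacement gradients are obtained by analytic chain-rule differentiation
of this representation through cylindrical coordinates and verified against
central finite differences of the evaluated field (1 µm step, < 1e-4
relative at generic points). Two representation-level facts matter for
interpretation:

- rigid motions are reproduced exactly (F = I to 1e-8);
- an affine field is reproduced only up to the angular discretization of
  the surface grid (value error O(dΘ²), gradient error O(dΘ) times the
  gradient amplitude), because Cartesian components are interpolated
  piecewise-bilinearly in (Θ, Z). This is intrinsic to the prescribed
  interpolation, not a bug; the corresponding strict oracle in the
  acceptance suite documents the gap.

**Incompressibility of the reconstructed gradient.** The radial gradient is
the least-constrained part of the reconstruction (the volumetric data fix
only a linear-in-R trend). By default the pipeline enforces det F = 1 by
rescaling the radial stretch only — leaving the well-measured in-plane and
axial components untouched — rather than the uniform F/J^(1/3) projection,
which smears radial error onto all axes and measurably biases the axial and
diagonal fiber moduli (20–30 % on the noiseless fixture, vs < 1 % with the
radial correction). The uniform projection remains available
(`incompressibility="isochoric"`); the constitutive isochoric split itself
always uses F̄ = F/J^(1/3) with the corrected F. The raw determinant is kept
as a diagnostic (J_raw; a warning fires if |J_raw − 1| > 0.05).

Incremental displacement chains (as produced by volume correlation between
consecutive states) are composed multiplicatively, updating evaluation
positions between increments; states below the reference invert increments
by fixed-point iteration. A purely additive accumulation is available for
comparison.

## Constitutive model

Per unit reference volume, wall points carry four fiber-family energies and
an elastin-matrix neoHookean term; thrombus points carry a separate
neoHookean term. Fiber families are circumferential (a₁ = e_c), axial
(a₂ = e_a) and two symmetric diagonals (a₃± = cos β e_c ± sin β e_a).
Constituents are deposited under prestretch: fiber deposition tensors
G_i = G a⊗a + (1/G)(I − a⊗a) (as printed; a unimodular 1/√G variant is
available behind `unimodular_deposition`, and does not affect
identification because only G_i a_i enters the equations), and the matrix
tensor G₄ = G⁴ e_c⊗e_c + G^a e_a⊗e_a + (G⁴G^a)⁻¹ e_o⊗e_o (unimodular by
construction). Fiber energies are Fung-type exponentials in the squared
prestretched fiber stretch I = |F̄ G_i a_i|², with a tension/compression
split ⟨I−1⟩₊ / ⟨I−1⟩₋ and the compressive branch weighted by α ∈ [0, 1].

The deviatoric Cauchy stress is the exact work-conjugate derivative of this
energy; in particular the compressive branch enters with a negative sign
(the derivative of ⟨I−1⟩₋² is −2⟨I−1⟩₋). Stress–energy consistency is
enforced by a finite-difference oracle at 1e-5 relative.

**Volumetric response.** No volumetric energy U(J) is modelled. The
material is treated as incompressible: kinematics report J ≈ 1, forward
simulation resolves the reaction pressure from boundary conditions, and the
identification is provably insensitive to any spherical stress because all
virtual strain fields are exactly trace-free.

**Derived metrics.** The linearized circumferential stiffness is a central
finite difference (δ = 1e-4, configurable) of the circumferential Cauchy
stress under a superposed circumferential stretch with isochoric radial
compensation, i.e. dσ_cc/d ln λ_c, reported in MPa. Reported
circumferential stress resolves the reaction pressure from the radial
traction boundary conditions as σ_cc ≈ dev σ_cc − dev σ_oo − p(1 − ξ),
which reduces to the Laplace value in the thin-wall limit (verified to 5 %
at h/r = 0.1, and to ~1 % in the volume mean against the half-cylinder
force balance p·r_i/h).

## Virtual fields identification

For every material sector (at its deformed centroid per load state) two
virtual fields are built, modulated by a Gaussian kernel
W = exp(−Δθ²/(10π/N_Θ) − Δz²/(5 L_z/N_Z)) (denominators exactly as
published; a squared-width variant is available for sensitivity studies):

1. a radial 1/r field, u* = (1/p_ref) W (x, y, 0)/(x²+y²), normalized by
   the reference pressure;
2. an axial extension field, u* = (1/F_ref)(−x/2 W, −y/2 W, Φ), normalized
   by the reference axial force, where Φ is the z-antiderivative of the
   kernel (closed form via erf). Using Φ instead of zW in the axial
   component makes the virtual strain *exactly* trace-free while reducing
   to the plain extension field wherever the kernel is flat in z.

Virtual strains are analytic and verified against finite differences of
u*; both families are exactly trace-free, so the indeterminate reaction
pressure never enters the identification. The fields are singular on the
axis (excluded inside a configurable r_min, never reached by wall points).

Internal virtual powers use one-point (deformed centroid) quadrature per
tet; because the integrand carries J⁻¹ and the deformed volume is J·V₀, the
quadrature weight reduces to the reference volume. The energy is linear in
the moduli c¹..c⁵ at fixed nonlinear parameters Ξ (k¹..k³, G¹..G⁴, β, α; 9
per sector, with the axial deposition stretch G^a global), giving a
rectangular system A(Ξ){c} = {P*_ext} with 2·N_Θ·N_Z·(number of states)
rows and 5·N_Θ·N_Z columns; c⁵ columns of thrombus-free sectors (and c¹..c⁴
columns of wall-free sectors) are removed rather than zeroed.

External virtual power takes the measured pressure on the deformed luminal
surface (traction −p n̂, facet-centroid quadrature, normals auto-oriented)
and the measured axial force on the end sections. The end traction
resultant is f + pπr_i² (transducer force plus the pressure-on-cap term),
paired with the area-averaged axial virtual displacement over the deformed
end annulus; it contributes only to the axial family, whose field alone has
an axial component.

{c} is solved by least squares (orthogonal factorization — algebraically
the printed normal-equations form, chosen for conditioning), with a
nonnegative re-solve if any modulus comes out negative. Rows are first
equilibrated by the inverse RMS external power of their virtual-field
family: the p_ref/F_ref prefactors are intended to bring both families to
comparable virtual-power magnitudes, but the raw reference force can still
leave the axial family more than an order of magnitude below the pressure
family, which makes plain least squares discard the axial information (the
axial modulus then becomes weakly identified and overfits noise). The
equilibration is applied consistently to A and P*_ext, i.e. a weighted
least squares with equal aggregate weight per family. The cost H(Ξ) is
the squared residual norm, algebraically identical to the printed projector
form (asserted to 1e-9 on random systems).

**Nonlinear optimizer.** Two seeded global optimizers are provided. The
real-coded genetic algorithm (tournament selection, blend crossover,
annealed Gaussian mutation, elitism; population 60, 120 generations by
default) mirrors the classical choice for this cost. In practice the cost
landscape of the 9-parameter sector problem is deceptive: a local basin
with k² and G³ pinned at their bounds and α inflated attracts both the GA
and simplex descent, while the true basin (cost ~50× lower) is found
reliably by differential evolution at a comparable evaluation budget.
`identify()` therefore defaults to seeded differential evolution (Sobol
initialization, popsize multiplier 15, 60 iterations) followed by a
Nelder–Mead polish of the best candidate; both the optimizer and its budget
are configurable. Default parameter bounds: c ∈ [0, 500] kPa,
k ∈ [0.01, 10], G¹..G³ ∈ [1.0, 1.3], G⁴ ∈ [1.0, 2.5], β ∈ [15°, 75°],
α ∈ [0, 1]; spans cover published murine aorta four-fiber fits and are
overridable per run. Any subset of the nonlinear parameters can be frozen
(`fixed`), which reduces the search dimension (and, with all nine frozen,
reduces identification to a single linear solve).

## Synthetic study conditions

No measured datasets are distributed; the generator produces the complete
input bundle from a forward model with known truth, under the measurement
protocol above:

- geometry: a thick-walled tube defined at the reference state, default
  luminal radius 0.65 mm, outer radius 0.85 mm (a dissection-thickened
  murine SAA), length 4 mm, λ^iv = 1.4; optional inner thrombus layer
  (full annulus, for exactly equilibrated layered solutions, or an angular
  span, for qualitative tests);
- truth parameters: c¹ = 15, c² = 10, c³ = 20, c⁴ = 30, c⁵ = 5 kPa,
  k¹ = 0.8, k² = 0.5, k³ = 1.2, G¹ = G² = G³ = 1.08, β = 40°, α = 0.1,
  G^a = 1.25 — inside the identification bounds and representative of
  murine aorta fits. G⁴ is not free: it is calibrated by a root solve so
  the reference state is exactly self-equilibrated at 80 mmHg (the
  deposition-prestretch property of the constrained-mixture model); the
  default set calibrates to G⁴ ≈ 1.223;
- mechanics: incompressible inflation–extension map
  r(R) = √(r_i² + (R² − R_in²)/μ) with μ the axial stretch relative to
  λ^iv; the inner radius solves the Laplace integral
  p = ∫(σ_θθ − σ_rr) dr/r (48-point Gauss–Legendre per layer, bracketed
  Brent root solve, overflow-safe bracketing); the transducer axial force
  is π∫(2σ_zz − σ_rr − σ_θθ) r dr;
- measurements: surface grid 50 × 30 (3 components), volumetric lattice
  48 × 48 in-plane × 100 axial slices masked to Ω, in-plane components
  only; seeded Gaussian noise, defaults 3 µm (surface) and 12 µm (volume —
  the mid-range of the reported volumetric displacement uncertainty of
  10–15 µm);
- mesh: structured hex-to-tet annular mesh, default ≈5 000 elements (tests
  use ≈2 000; the power-balance oracle ≈20 000). These sizes are chosen so
  a full identification runs in minutes on one core.

What the generator does **not** emulate: correlation drop-out and spatially
correlated DVC noise, curved centrelines and branch ostia, false-lumen
geometry (the thrombus is an annular layer or sector, not a dissected
flap), mounting-induced axial nonuniformity, and angularly heterogeneous
properties with exact equilibrium (angular heterogeneity violates the
axisymmetric closed-form equilibrium and is offered only with a documented
relaxation, for ordering tests). Passing recovery tests therefore
demonstrate correctness of the estimator under the stated measurement
model, not robustness to every pathology of real lesions.

Measured behaviour on the default study conditions (recomputed by
`scripts/acceptance.py`): row-wise virtual-power balance < 2 % on the
noiseless fixture; moduli c¹..c⁴ recovered within 5 % noiselessly and
within 20 % at 12 µm volumetric noise through the full
sample → fuse → identify pipeline.

## Histology

Sections are classified per pixel by nearest reference color in CIELAB
(palette defaults are stand-ins for instrument calibration; ties break
fibrin > collagen > elastin > other), partitioned 25 circumferential × 5
radial between per-ray tissue boundaries around the section centroid, with
"other" absorbing the remainder so fractions sum to 1. Thickness profiles
are ray-based (outer minus inner boundary radius per angle, periodic moving
average); the Eulerian PDE thickness transform used historically is an
acknowledged alternative with the same output contract. Registration to the
mesh thickness map minimizes the integrated squared difference of
relative (max-normalized) thickness over rotation and axial position
(1° × slice-spacing grid scan, then Nelder–Mead). Because each profile is
normalized by its own maximum while the mesh map is normalized globally,
the cost floor is generally nonzero and the axial direction is softer than
the rotational one; rotation recovery is accurate to ~1° on non-degenerate
profiles. Correlations are Pearson and Spearman with two-sided p-values
(significance at P < 0.05).

## Known limitations

- The linear-in-R transverse blend cannot represent the curvature of the
  true transmural displacement profile; on the default geometry this keeps
  reconstruction error under 2 µm near the working pressure range but
  grows at strongly collapsed low-pressure states.
- Nonlinear parameters are weakly identified: distinct Ξ with compensating
  moduli produce nearly identical costs. The moduli are robust (the
  quantity the method is designed for); individual k, G, β, α estimates
  should be read with caution.
- The axial-force pairing assumes the end tractions are statically
  equivalent to a uniform axial traction; shear at the ends is neglected.
- Sector-wise constant parameters produce blocky maps by construction;
  empty sectors are rank-deficient and reported, not silently filled.
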