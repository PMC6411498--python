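# Methods

`tubemorph` implements a surface-based morphometry analysis for elongated,
tube-like subcortical structures (the motivating case is the hippocampus in
carriers of zero, one or two copies of a genetic risk allele — groups NC,
HT and HM). This note documents the models and algorithms, the parameters
that matter, and the choices made where the design was genuinely open.

## The analysis model

Each subject contributes a closed genus-zero triangle surface per side,
assumed already linearly registered to a common space (the affine comes
from the mask header; it is never estimated here). The pipeline establishes
dense cross-subject correspondence and tests, vertex by vertex, whether the
local geometry differs between groups.

### 1. Mask to surface (`tubemorph.mesh`)

Binary masks are closed morphologically, reduced to their largest
26-connected component (clusters below `min_component_voxels` are treated
as stray segmentation voxels and dropped), upsampled 3x with a light
Gaussian (sigma 0.4 fine voxels) and triangulated by marching cubes at the
0.5 isolevel, with voxels as cell-centred samples. The topology guarantee —
a closed genus-zero output — is enforced by construction plus an explicit
Euler-characteristic check rather than by a topology-preserving level-set
evolver; the contract (genus-zero output or a `TopologyError`) is the same,
and the substitution is deliberate. The upsample/smoothing pair was chosen
so that a single 1 mm voxel reconstructs within 30% of its voxel volume
while a 10 mm digital ball reconstructs within 2% of the analytic sphere
volume; coarser settings fail the former, stronger smoothing the latter.

Resolution adjustment to the analysis budget (default 15,000 vertices per
side) uses loop subdivision with projection back onto the input surface
when below target and link-condition-checked shortest-edge collapses when
above, followed by a sampled symmetric Hausdorff check (default budget 1%
of the bounding-box diagonal). Enclosed volume is the absolute
signed-tetrahedron sum and is reported in the registered space.

### 2. Correspondence (`tubemorph.correspondence`)

**Cuts.** Two cuts open each surface into a topological annulus. The cut
axis is the leading eigenvector of the vertex second-moment tensor (an
`AmbiguityError` with instructions is raised when the top two eigenvalues
are within 5%, as for a sphere); the extreme 2% of the axial extent is
removed at each end. Boundary "ear" faces whose three corners all lie on
one cut loop are removed — they would degenerate in the parameter domain.

**Conformal parameterization.** The axial coordinate u solves the Laplace
equation with cotangent weights (clamped at a small positive floor for
obtuse-triangle robustness), u = 0 on the posterior cut and u = 1 on the
anterior cut. The angular coordinate v is the conjugate harmonic function:
the 90°-rotated gradient of u is integrated in the least-squares sense on
the mesh cut along a steepest-ascent seam, and then re-solved with the
period *prescribed* — every seam jump is forced to equal the median free
jump — because free jumps deviate from the period by discretisation and
would otherwise leave a distortion ridge along the seam. v is normalised to
period 1; the quasi-conformal dilatation diagnostic undoes that global
rescaling (the isothermal pair is (u, period·v)) so that it measures angle
distortion only. Isolated flipped parameter triangles (obtuse or noisy
inputs) are repaired by local neighbour-average relaxation; if any flip
survives, a `QualityError` reports the count.

**Gauge.** The rotational gauge anchors v = 0 on the u = 0 loop at the
vertex most aligned with the tube's bow direction (the off-axis offset of
the surface centroid). The vertex-farthest-from-the-axis rule is kept as a
fallback for straight tubes, but on bent tubes the cut plane slices the
tilted end ring and removes exactly the far-side vertices, leaving that
rule a near-tie; the bow direction is stable against both noise and cut
tilt.

**Grid resampling.** Geometry, the conformal factor (local 3D area per
parameter area) and mean curvature are interpolated barycentrically onto
the regular grid u_i = i/(n_u−1), v_j = j/n_v (default 100 x 150 = 15,000
nodes). Candidate triangles come from a KD-tree; the rare stragglers it
misses (very anisotropic faces near the cuts) are resolved by an exact
scan, and only genuinely uncovered nodes count toward the 1% fallback
budget.

**Fluid registration.** Subject grids are registered to the template grid
by multichannel demons on the z-scored (log conformal factor, mean
curvature) feature image — the cut-boundary rows inherit interior
curvature values, features are presmoothed (sigma 0.5 cells) and
winsorised at 4 SD. Velocity fields are Gaussian-smoothed (fluid, sigma 2
cells) with a light diffusion of the accumulated field (sigma 0.5),
periodic in v, with zero axial displacement on the cut rows. Steps are
accepted only if the sum-of-squares mismatch decreases (so the convergence
log is monotone) and only if the face-level Jacobian determinants of the
total map stay above half the regrid threshold; the integer angular gauge
is initialised by a circular search over world-space grid positions
(conformal features alone are ambiguous up to a half-turn on
near-elliptical cross-sections, and subjects share a registered world
frame). Forward and backward problems are solved jointly and each field is
averaged with the inverse of its counterpart; the 95th-percentile
composition residual is recorded against `ic_tol` (default 0.1 cells).
Because averaging two fold-free fields can graze a fold, the averaged
field is relaxed by light smoothing until strictly orientation-preserving.
The flip criterion is face-level — the signed areas of both triangles of
every mapped grid quad — which is exactly what the feature stage
differentiates, so a field passing registration cannot fold downstream.

### 3. Morphometry (`tubemorph.morphometry`)

Per grid face, the 2x2 Jacobian J = [w3−w1, w2−w1][v3−v1, v2−v1]^{-1} maps
the template parameter triangle to its image under the registration. (The
second column of the inverted matrix is v2−v1; the repeated-column variant
sometimes seen in print is singular by construction and cannot be meant.)
Per-vertex tensors average J Jᵀ and det J over incident faces, area-
weighted, *before* the matrix logarithm — preserving positive-definiteness
— and the three unique entries of log √(J Jᵀ) = ½ log(J Jᵀ) form the mTBM
triple (m11, m12, m22). The alternative order (log, then average) is a
different estimator and is deliberately not used.

The radial distance is the Euclidean distance from the registered subject
surface point (subject geometry sampled at the template node's mapped
coordinates) to the centroid of its own grid ring — the tube's medial
core. A config switch measures against the template's core instead.

**Directionality determinant.** The det J carried into ratio maps is the
determinant of the *surface* map differential: the parameter-plane
determinant times the conformal-factor ratio λ_subject(φ(x))/λ_template(x),
i.e. the local surface-area change, so atrophy gives det J < 1. This
matters: a conformal parameterization allocates *more* parameter area to a
thinned region (for a tube of radius r(z), du/dz ∝ 1/r), so the raw
parameter-plane determinant alone moves in the **opposite** direction under
atrophy and would invert the ratio map's interpretation. The parameter-
plane determinant is kept alongside (`det_j_param`).

### 4. Group statistics (`tubemorph.stats`)

Per vertex, the two-sample statistic is

    M = (N_S N_T / (N_S + N_T)) (S̄ − T̄)ᵀ Σ⁻¹ (S̄ − T̄)

with Σ the pooled covariance of the 4-dimensional features (Hotelling's T²
up to a constant; the squared form is used — permutation inference is
invariant to the monotone square root). Ill-conditioned Σ (normalised
determinant below 1e-8, the determinant analogue of a ~1e8 condition
bound at dimension 4) receives diagonal shrinkage (γ = 0.1).

Inference is a two-level permutation scheme with a common label
permutation across vertices per repetition. The observed labelling is
member 0 of the family {observed} ∪ {n_perm relabellings}, and every
member's p-map is its leave-self-in rank within that family divided by
(n_perm + 1) — for the observed map this is exactly the usual
p(v) = (#{M_perm ≥ M_obs} + 1)/(n_perm + 1), never zero, with ties
counting toward the numerator (`ties='gt'` restores strict ranking). Each
member's p-feature (count of vertices below α) is then compared with the
observed one, and the map-level corrected p is again
(count + 1)/(n_perm + 1). Computing the whole family through one code
path matters: it makes the observed and permuted p-maps exchangeable
under the null, so the corrected p is uniform up to tie handling.
Asymmetric variants (ranking permutations only among themselves, or
comparing a double-precision observed statistic against single-precision
permutation statistics) visibly bias the corrected p whenever the null
p-feature distribution is narrow. The permutation
path works on the ten unique pooled-covariance entries in float32 with a
machine-generated adjugate (the loop is pure rank information; single
precision is ample), with a relative tie tolerance of 1e-4 against the
float64 observed statistic so the identity relabelling registers as a tie.
Memory is bounded by chunking vertices.

Ratio maps divide group-mean surface det J (reference group first); CDF
diagnostics plot sorted p-values against uniform quantiles and summarise
the maximum deviation above the diagonal. Volume contrasts use a
two-sided permutation test of the group mean difference with the same
estimator. Demographic matching uses one-way ANOVA reconstructed exactly
from per-group means, sample SDs (n−1 divisor) and sizes, and Pearson's
chi-squared without continuity correction.

## The synthetic cohort model (`tubemorph.synthetic`)

The generator emulates the study conditions downstream stages are tested
under: three groups of 44/36/37 subjects by default, each a deformation of
a common tube template (50 rings x 30 around for generation — deliberately
decoupled from the analysis-grid resolution), length 40 mm, base radius
5 mm, planar bow with amplitude 0.3 of length, elliptical cross-section
with flattening 0.15 (semi-axes r(1±e)). The bend and flattening emulate
the curved, oval geometry of real subcortical tubes and make the angular
gauge geometrically well defined; flattening is kept moderate because the
combination of bend and strong flattening degrades the conformality of the
discrete parameterization near the cuts.

Per subject, the template is deformed by (i) a band-limited random normal
field — axial basis cos(πku), k = 1..3, angular harmonics up to order 2 —
rescaled to an exact pointwise RMS of `subject_variability_sd` (0.3 mm
default; the axial basis integrates to ≈0 along the tube so the field
barely perturbs volume); (ii) an inward "atrophy patch": a raised-cosine
taper in parameter-domain distance (v periodic) around (u, v) =
(0.5, 0.25), radius 0.25, with inward magnitude per group 0 / 0.5 / 1.2 mm
(NC / HT / HM); and (iii) isotropic i.i.d. vertex noise (0.05 mm). Subjects
failing a sampled validity proxy (any face flipped against its template
normal, or degenerate) are regenerated from a derived sub-seed and logged.
Every generator is a pure function of its spec and seed.

The default effect magnitudes and patch size were calibrated — as the
generator's own stated design rule — so that the highest-dose contrast
reaches map-level corrected p < .05 at the default group sizes, with the
patch covering ≈20% of the surface; a patch much below ~7% of the surface
is structurally hard for the p-feature correction to detect, because the
null expectation of the p-feature is already 5% of vertices.

What the generator does **not** model: realistic hippocampal anatomy
(subfields, digitations), segmentation error structure, scanner intensity
artefacts, or spatially correlated noise beyond the smooth subject field.
Passing the synthetic suites therefore demonstrates the pipeline's
statistical calibration and its ability to localise a known, smoothly
tapered, single-patch effect on tube geometry — not performance on real
segmentations.

Demographics are drawn per group from configurable normal distributions
(sex multinomial), with defaults matching the moments of a demographically
matched three-group study table.

## Problem sizes for the test and acceptance runs

The simulation-based suites run at a scaled-down size chosen as this
package's own desk-scale default: analysis grid 30 x 50 (W = 1,500),
1,000 permutations, cohorts of 16/13/13 for the dose studies (20
replicates) and 5 vs 5 for the null-calibration studies (200 replicates,
registration capped at 50 iterations — null subjects are near-aligned and
the calibration property must hold under any registration budget). Groups
of 5 are the smallest whose randomization distribution is fine-grained
enough for uniformity to be testable: with 4 vs 4 there are only
C(8,4)/2 = 35 distinct label splits, so the corrected p has atoms of
~0.03 and is intrinsically conservative at the 5% level. The
full-size defaults (W = 15,000, 10,000 permutations, 44/36/37) remain the
package defaults used by the pipeline.

## Numerical choices and degenerate inputs

- Cotangent weights clamped at 1e-8; Dirichlet systems solved with a 1e-12
  diagonal regulariser (SuperLU).
- Marching cubes level fixed at 0.5 on the (upsampled, lightly smoothed)
  binary grid; 0-based voxel indices map through the NIfTI affine.
- The scanline rasteriser offsets sample points by sub-voxel epsilons with
  a strict-interior counting rule, so axis-aligned faces are not
  double-counted.
- 2x2 symmetric eigendecompositions are closed-form with a degeneracy
  guard at repeated eigenvalues.
- Zero within-group variance in ANOVA returns F = ∞, p → 0 with a
  `degenerate` flag (or F = 0, p = 1 when the means also coincide).
- Empty significance masks produce an all-NaN ratio map with a warning,
  not an error; identical volume lists give p = 1 with a warning.

## Known limitations

- The demons solver recovers the moderate, smooth deformations the
  generator produces; very large rotations (beyond the integer-shift
  initialisation) or non-smooth deformations are out of its basin.
- The jagged cut boundary leaves a one-to-two-row band of elevated
  quasi-conformal dilatation at u ≈ 0 and u ≈ 1; interior distortion is
  small (95th percentile ≈ 1.3 on the default template).
- A dent changes the conformal structure globally, so very large cohorts
  can detect small far-field effects of a purely local deformation; the
  p-feature then saturates across dose levels even though the local effect
  ordering is preserved at moderate sample sizes.
- Left/right structures are processed as separate studies; no bilateral
  model is provided.
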