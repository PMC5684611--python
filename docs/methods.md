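# Methods

This note records the modelling assumptions, numerical choices and known
limitations of `elfdosim`. It documents what the code computes and why the
defaults are what they are; every number quoted here is produced by the
package's own tests or scripts.

## Physical model and its assumptions

The exposure scenario is a body-sized conductor in a perfectly homogeneous
sinusoidal magnetic flux density **B** at 50 Hz. Three approximations define
the regime:

1. **Magnetoquasistatics.** The body (< 1 m) is vastly smaller than the
   free-space wavelength at 50 Hz (6000 km), so the source field is
   unperturbed by the body and the vector potential can be written directly
   as **A** = ½ **B** × (**r** − **r**c). The gauge point **r**c is the
   centroid of the conductive region; any other choice changes **A** by a
   gradient that the scalar potential absorbs, leaving **E** unchanged.
2. **No displacement currents.** At 50 Hz tissue conductivities
   (0.02–2 S/m) dominate ωε by orders of magnitude, so charge relaxation is
   instantaneous and current conservation reads ∇·σ**E** = 0. Tissue
   permittivities are carried in the data model to document the
   approximation but never enter the solver.
3. **Single frequency, linear materials.** Fields scale linearly with B and
   with frequency; the solver exploits this by substituting Φ = jωψ, which
   turns the complex-valued scalar-potential equation into one real,
   symmetric positive-semidefinite system, and |E| = ω|∇ψ + **A**|.

**B-amplitude convention.** The 200 µT source amplitude is treated as an
RMS value so that every reported field value is RMS, which is what the
percentile metric compares against regulatory limits. Treating it as a peak
amplitude instead would scale all outputs by 1/√2; the convention is echoed
in every output header and in run metadata.

**Orientation parametrization.** The field direction is
b = (sin θ cos φ, sin θ sin φ, cos θ) in a body frame with z vertical
(θ = 0 is the TOP orientation), x anteroposterior, y mediolateral. θ and φ
are modelled as independent uniform random variables on [0°, 180°] and
[−180°, 180°] — the maximum-entropy choice given only range information.
The parametrization is degenerate at θ ∈ {0°, 180°} (φ irrelevant there);
this is accepted as-is and the surrogate treats (θ, φ) as plain independent
coordinates. The cost is a mild redundancy near the poles, not a bias: the
surrogate is only ever evaluated against the same measure it was trained
under.

## Discretization and solver

The conductor is a rectilinear isotropic voxel grid of labelled tissues.
The PDE −∇·σ∇ψ = ∇·σ**A** is discretized cell-centred with a 7-point
finite-volume stencil; conductivity on a cell face is the harmonic mean of
the two adjacent voxels, which makes a face with air on either side carry
exactly zero conductance and so imposes the zero-normal-current boundary
condition σ(∂ψ/∂n + **A**·n) = 0 naturally. The source term is assembled in
flux form (per-face σ_f **A**·n), which telescopes across interior faces:
the discrete right-hand side sums to zero exactly, so the singular Neumann
system is consistent. The constant null space is handled by solving with
conjugate gradients (Jacobi preconditioner, relative residual 10⁻⁸,
iteration cap 2000·m^(1/3) for m unknowns) and removing the mean over
conductive voxels afterwards — a node-choice-independent gauge.

The electric field is evaluated at voxel centres as the mean of the two
face derivatives per axis; an interior face contributes the difference
quotient, a conductor–air face contributes the boundary condition's exact
value ∂ψ/∂n = −**A**·n. Using the boundary condition instead of a one-sided
difference suppresses part of the spurious field spikes a staircased
surface otherwise produces.

**What converges and what does not.** On an axis-aligned box (voxelization
exact) the computed field converges cleanly to an independent fine-grid
reference (−5.3 % → −2.3 % → −0.8 % maximum-field error at 4/2/1 mm in the
package's validation experiments). On a voxelized sphere, however, the
*pointwise maximum* of |E| does not converge: the staircase surface has
genuine re-entrant corners whose local field enhancement the discrete
solution resolves better and better as the grid is refined (observed
+10 → +17 % overshoot of the smooth-sphere maximum between 4 mm and 1 mm).
This is a property of the jagged geometry, not a solver defect, and it is
precisely why the dosimetric metric below uses a percentile of a spatially
averaged field rather than a raw maximum. Convergence statements in the
tests therefore use the relative L2 field error (17 % → 12 % → 8.6 % at
4/2/1 mm for a 7 cm sphere) and the percentile metric (within 3 % of its
closed-form value at 2 mm), not the raw pointwise maximum.

The homogeneous sphere admits the closed form |E| = π f B ρ (ρ = distance
from the axis through the centre along **B**), independent of σ; its 99th
percentile over the ball is π f B R √(1 − 0.01^(2/3)). Both are used as
oracles.

## Exposure metric

Per tissue: vector-average the field over a cube of 2 mm side slid over
every voxel, restricted to voxels of the same tissue label (clipped at the
boundary), take the magnitude, then the 99th percentile over the tissue's
voxels (linear interpolation between order statistics). Design choices:

- *Sliding, tissue-restricted cubes* rather than disjoint blocks: a
  block partition would make the metric depend on the arbitrary block
  phase, and crossing tissue boundaries would mix materials of different
  conductivity.
- *Vector average then magnitude*: in this solver all field components
  share a common phase, so the alternative (average of magnitudes) differs
  only at cubes straddling field reversals; the chosen order is the one
  that corresponds to averaging the physical field.
- For even cube-to-voxel ratios the averaging kernel is a symmetric
  trapezoid (half-weight end planes) so the window stays centred; a plain
  box of even length would shift the metric by half a voxel.
- Tissues below 64 voxels are refused: a 99th percentile of fewer values
  is dominated by single voxels.
- The whole-CNS value is the maximum of the per-tissue E⁹⁹ᵗʰ over CNS
  tissues.

## Experimental design and surrogate

Designs are the first N points of the unscrambled 2-D Sobol sequence mapped
affinely onto the (θ, φ) rectangle. Unscrambled standard direction numbers
make every design reproducible across machines and nested across sizes
(the first n rows of a 2n-design are the n-design), which is what lets the
adaptive loop grow the design without discarding forward solves. The
sequence's all-zeros first point maps to (θ=0°, φ=−180°), a valid
orientation, and is retained.

The surrogate basis is the total-degree simplex j₁+j₂ ≤ p of tensor
products of *orthonormal* Legendre polynomials (L̃_j = √(2j+1) L_j) in the
inputs affinely mapped to [−1, 1] by their fixed distribution ranges — the
distribution, not the sample, defines orthogonality. Orthonormal scaling is
what lets output variance and Sobol indices be read directly off squared
coefficients.

Coefficients are estimated by hybrid LAR: Least Angle Regression on the
standardized basis matrix ranks candidate terms; each prefix of the LAR
path is then refit by ordinary least squares on the raw basis, scored by
the exact hat-matrix leave-one-out error (mean((e_i/(1−h_ii))²)/var(y),
bit-equivalent to explicitly refitting each fold of an OLS model), and the
best-scoring prefix is kept. Unselected coefficients are exactly zero, the
fit is fully deterministic, and saturated or rank-deficient prefixes are
skipped. The absolute (variance-normalized) LOO criterion is used *inside*
the fit because it is well defined even when some observation is zero; the
*reported* validation quantity is the relative-error pMSE below.

## Validation loop

The acceptance criterion is the percentage mean-square leave-one-out error
pMSE = 100·(1/N)Σ((y_i − ŷ_i)/y_i)², computed by explicit refitting on each
leave-one-out fold (no shortcut), with a 5 % threshold. The relative form
is kept exactly as defined — it is scale-free, which suits a metric spanning
tissues of different size — at the price of being undefined when y_i = 0;
such observations are refused with an explicit error.

The adaptive loop starts from the thumb-rule size N = (M−1)P (21 for M = 2,
p = 5), tries degrees in the order p₀, p₀−1, p₀+1 at each N (preferring the
nominal degree), and grows the design by Sobol continuation in steps of 3,
reusing every cached forward evaluation. Hard caps N ≤ 200, p ≤ 8 return
the best configuration seen, flagged unaccepted. On the package's smooth
synthetic phantoms the loop accepts at the initial 21-point design with
pMSE ≪ 1 %; the step size 3 keeps both the thumb-rule start (21) and a
30-point acceptance reachable exactly.

## Exposure analysis

The surrogate is sampled at 10 000 Sobol orientations with a sequence
offset of 4096 — disjoint from any training design the loop can reach — so
the analysis never evaluates the surrogate preferentially at its own
training nodes. Reported per tissue:

- median, quartiles, extremes and QCD = (Q₃−Q₁)/(Q₃+Q₁) (quartiles =
  25th/75th percentiles, linear interpolation, consistent with the metric);
- first-order Sobol indices from the coefficients: with D = Σ_{j≠0} α_j²,
  S_θ sums α² over indices with j₁>0, j₂=0 and S_φ symmetrically; the pair
  is normalized to unit sum. First-order (not total) indices are used
  because after normalization the reported ratio is the same either way up
  to the interaction share, which the normalization distributes implicitly;
- high-exposure orientation patterns: orientations predicting more than
  90 % of the sampled maximum are folded to sign-invariant directions
  (opposite polarizations are physically equivalent for this source),
  assigned to the nearest body axis by absolute dot product, and each
  present axis is reported with the maximal |Δθ|, |Δφ| deviations of its
  qualifying points from the axis's reference orientations.

The mean stochastic model averages K observation vectors sharing one design
element-wise and runs the identical fit + validation pipeline on the mean;
by linearity of least squares the result for in-span responses is the mean
of the individual models.

## Synthetic phantoms

The generator replaces proprietary anatomical models with three families:

- **Sphere / ellipsoid**: one homogeneous CNS tissue; used for oracle
  validation (sphere) and as the smooth, anisotropy-bearing standard test
  case (ellipsoid).
- **Child phantom**: trunk ellipsoid + neck + head sphere (muscle-like,
  0.2 S/m), brain grey-matter shell (0.10 S/m) with white-matter core
  (0.065 S/m), two or more deep nuclei (0.10 S/m), a spinal cord cylinder
  (0.08 S/m) and thin horizontal nerve tubes (0.03 S/m, PNS). Primitives
  are painted innermost-last (later entries overwrite earlier ones — the
  deterministic nesting rule); the seed jitters only nucleus centres and
  nerve take-off heights, emulating inter-individual segmentation
  differences. Conductivities are typical 50 Hz literature values for these
  tissue classes, chosen once. Grid dimensions are forced odd so the body
  axis passes through voxel centres, keeping thin-cylinder voxel counts
  within a few percent of their analytic volumes.

What the generator does **not** emulate: anatomical realism (gyri, CSF,
bone, skin layers), age-dependent morphology, posture, or heterogeneous
dielectric maps. Consequently, passing tests demonstrate the correctness of
the pipeline — solver, metric, surrogate, statistics — not the numerical
exposure values of any real child; per-tissue results for real anatomies
depend on tissue shape, position and surroundings, which is exactly the
sensitivity the orientation-pattern analysis exposes (an elongated tissue
is most exposed when **B** is parallel to its long axis, maximizing
induced-loop area; a spherical tissue is orientation-blind, QCD ≈ 0).

## Problem sizes and defaults

| quantity | default | note |
| --- | --- | --- |
| voxel size | 2 mm (validation fixtures), 4 mm (child phantom, large-ellipsoid script) | the test-suite ellipsoid is ~60³ voxels; the acceptance script uses the full child-sized semi-axes 0.09/0.12/0.30 m at 4 mm |
| solver tolerance | 1e-8 relative residual | well below every assertion tolerance |
| cube side | 2 mm, floored at one voxel | degenerate cube = per-voxel magnitude |
| degree p₀ | 5 | standard working degree for two smooth inputs; search tries 4 and 6 |
| threshold | 5 % pMSE | acceptance criterion for the surrogate |
| analysis sample | 10 000 Sobol points, offset 4096 | disjoint from training |
| pattern fraction | 0.9 of the sampled maximum | |

## Known limitations

- Staircase boundaries make pointwise field maxima non-convergent (see
  above); only averaged/percentile quantities should be compared across
  resolutions.
- The LOO pMSE in its relative form is fragile when observations approach
  zero; the pipeline refuses rather than regularizes such cases.
- Isotropic conductivity only; no frequency sweeps; no non-uniform sources.
- The orientation-pattern half-widths depend on the sampling density
  (10 000 points) near the qualifying set's boundary; they are descriptive,
  not confidence intervals.
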