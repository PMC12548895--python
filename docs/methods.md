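# Methods

This note documents the models and numerical choices behind `morphomap`:
a pipeline for quantifying tissue motion and deformation during
organogenesis from fragmented 3D+t live-imaging data, developed around
the case of early mouse heart-tube morphogenesis (the cardiac crescent
closing and elongating into the primitive heart tube).

## The problem

Live two-photon acquisitions of a developing organ cover only a few
hours and often miss parts of the tissue (typically the inflow and
outflow tracts of the forming tube). No single movie spans the
developmental window of interest, so movies from different embryos —
each in its own orientation, with its own coverage — must be integrated
into a common spatiotemporal reference before tissue-scale deformation
can be measured and compared. The pipeline does this in four stages:
per-movie motion estimation, staging + spatial mapping into a reference
Atlas, continuum-mechanics deformation measurement, and cross-stage
concatenation into cumulative deformation maps and an in-silico fate
map.

## Motion estimation (free-form deformation registration)

Consecutive frames are aligned by a cubic B-spline free-form deformation
T(x) = x + u(x), where u is interpolated from a regular lattice of
control-point displacements. The target function is

    E(u) = (1/N) Σ_x (I_ref(x) − I_mov(T(x)))² + λ E_reg(u)

with SSD similarity (consecutive live frames are similar enough that an
intensity-difference measure suffices) and a discrete-Laplacian bending
energy on the control lattice as E_reg. Defaults: lattice spacing 10 µm
(half an average cardiomyocyte diameter — for synthetic scenes the same
rule gives half the synthetic cell diameter), λ = 0.01, stopping at a
relative energy change of 1e-8 or 100 iterations per level, four
resolution levels (image and lattice halved per level, coarsest first).
Each level is minimized by L-BFGS-B with the analytic gradient; the
gradient of the SSD term with respect to the control points is computed
by the exact adjoint of the separable B-spline interpolation operator.
The dense B-spline evaluation uses the spline-coefficient convention
(`map_coordinates(..., prefilter=False)`), for which a zero lattice is
exactly the identity map and constant/linear lattices reproduce
constant/linear fields exactly — several tests rely on this to construct
exact analytic transform sets.

A sequence of N frames is registered pairwise outward from the midpoint
frame floor(N/2) ("bidirectional" anchoring): forward fields cover
anchor→N−1 and backward fields anchor→0. Any quantity defined at the
anchor (segmentation mask, mesh nodes, landmarks) is carried to all
other frames by chaining the pairwise fields; anchoring at the midpoint
halves the longest chain, and the acceptance suite verifies that the
accumulated tracking error is never worse than frame-0 anchoring.
Out-of-domain points are clamped to the volume boundary and flagged
rather than dropped, because meshes may graze the volume edge.

Field direction convention: the recovered field maps reference-frame
(earlier-frame, on the forward side) coordinates to moving-frame
coordinates, which is the direction point propagation needs. This
convention is pinned by the ground-truth-flow tests, not assumed.

## Surfaces and Live-Shapes

The myocardium is thin (1–2 cell layers), so the tissue is modelled as a
triangular surface mesh. Meshes are extracted from binary masks by
marching cubes on the mildly smoothed indicator (σ = 1 voxel; contouring
the raw binary field inflates area by several percent through
stair-casing), keeping the largest component and enforcing outward
normals; the result is genus-0 for simply connected masks. Laplacian
smoothing with weight 0.9 and 5 iterations is the standard surface
clean-up. Rasterization back to voxels uses voxel centers offset half a
pitch from the mesh bounds (so axis-aligned faces never coincide with
center planes) and an inside test against the outward normal of the
nearest surface sample; closed-mesh round trips preserve volume to a few
percent. Thin-shell masks (the tissue itself, no interior fill) serve
the Atlas-projection step.

A "Live-Shape" is one mesh topology with per-frame node positions
obtained by propagating the anchor-frame mesh through the transform set.
Node identity is material identity: no remeshing over time, so any frame
pair supports per-face deformation analysis.

## Staging

Frames are assigned to Atlas groups (Gr1..Gr10; Gr10 excluded from
calibration, Gr1 from deformation analyses) by a morphometric feature:
the ratio h/w of two landmark distances (h: ventricle elongation, w:
distance between the inflow borders), computed from seven landmarks
pt1..pt7. Landmarks are placed once at the anchor frame (median of
replicate placements) and carried to all frames by the motion profile.
pt7 is found automatically as the exit point of the first principal axis
of the mesh, with node weights of one-third the incident face area
(faces are unevenly sized and unweighted PCA can tip the axis); an
orientation hint resolves the axis sign, and near-degenerate leading
eigenvalues (within 1%) require the hint.

The staging model is a Gaussian mixture over groups: per-group mean and
sd of h/w from calibration specimens, equal priors (group sizes are
small and no prior is better justified). A frame's posterior over groups
is the mixture responsibility at its h/w value; the label is the argmax.
The leading and trailing runs of frames sharing the first (resp. last)
assigned group are treated as the uncertain acquisition boundary and
keep their label only with posterior > 0.75. Per group, the
representative frame is the one with the highest posterior (ties toward
the earlier frame). The feature `s` (pt5–pt6 distance) is computed and
reported by convention but not used for staging; only h/w drives the
assignment.

## Rigid alignment (Student's-t mixture)

Shapes are aligned to the Atlas by a similarity transform (rotation,
translation, isotropic scale) estimated by EM over a Student's-t mixture
whose components sit at a random half-subsample of the source nodes
(3 degrees of freedom by default — heavy tails down-weight points with
no counterpart, which is exactly the situation with cut inflow/outflow
tracts; 150 EM iterations maximum). Clouds are centered and brought to
unit rms before EM so densities are scale-independent. Initialization
matters: elongated, near-tubular shapes have near-degenerate minor PCA
axes whose order can swap between a full and a cut cloud, so the EM is
warm-started from all 24 proper PCA axis alignments (plus identity) on
subsampled clouds, and the two best warm runs by log-likelihood are
refined on the full clouds. ICP (with mutual-nearest-neighbour trimmed
correspondences) and a Gaussian-mixture CPD variant (uniform outlier
component, weight 0.1) are provided as baselines; the acceptance suite
checks that the t-mixture is never worse than ICP on trimmed/outlier
instances. RMSE is reported over mutual nearest-neighbour pairs so that
deliberately missing regions do not dominate the score. ICP's known
failure modes are kept visible rather than patched: large unguided
rotations can stall in a local minimum (flagged by the reported RMSE),
and on smooth surfaces one-sided NN correspondences permit tangential
sliding.

"AtlasCut" removes Atlas nodes farther than a threshold from every live
node after rigid alignment (default threshold: 3× the live mesh's median
node spacing, recorded in provenance), replacing the original
interactive selection with a reproducible rule.

## Atlas projection (SurfaceMap)

A staged live mesh is projected into its Atlas group in four recorded
steps: (1) rigid t-mixture alignment of the Atlas onto the live mesh;
(2) AtlasCut; (3) both shapes rasterized to thin-shell masks on a shared
grid (default 2 µm pitch, Gaussian-smoothed, σ = 1 voxel), non-rigid
registration of the live mask onto the AtlasCut mask, and the recovered
field applied to the live nodes — the morph runs in the live pose frame,
and the rigid alignment is then inverted so the SurfaceMap lands in the
Atlas's own coordinate frame; (4) nearest-centroid matching from every
Atlas face to the morphed mesh. The SurfaceMap keeps the live topology
exactly: the geometry is standardized, the specimen's own dynamics are
preserved. Mapping quality is scored by transferring the live face-area
pattern through the correspondence and Spearman-rank-correlating it with
the area pattern actually sitting at each Atlas location (threshold 0.8
on synthetic projections; a permuted correspondence scores ≈ 0).

## Deformation mechanics

Between two states of a Live-Shape, each triangle's rest and deformed
edge vectors are expressed in local orthonormal in-plane bases
(Gram–Schmidt on the two edges), giving 2×2 frames R and T and the
deformation gradient F = T R⁻¹. Derived quantities per face:

* growth rate J = det(F), the area ratio (1 isochoric, >1 expansion,
  <1 compression); identical to the face-area ratio to 1e-9 and
  multiplicative under composed deformations;
* strain ε = ½(FᵀF − I). The pipeline computes the printed formula,
  which is the Green–Lagrange tensor (the right Cauchy–Green tensor
  proper would be C = FᵀF; the naming is occasionally conflated in the
  literature);
* anisotropy θ = σ_max/σ_min, the ratio of the principal stretches
  (singular values of F), with the major right-singular vector lifted to
  3D as the stretch axis. θ is deliberately defined on stretches rather
  than on ε's eigenvalues: strain eigenvalues vanish or change sign
  under compression and make a ratio ill-posed, while both readings
  agree that uniform scaling and rigid motion give θ = 1.

All quantities are invariant to rigid motions of either state and to the
choice of in-plane basis (property-tested to 1e-9). Values are attached
to the deformed-state mesh and smoothed by the unweighted mean over a
geodesic face neighbourhood (default radius 20 voxel-units, converted to
µm; geodesic distance is the shortest path on the face-adjacency graph
with centroid-to-centroid edge weights) to suppress isolated events such
as uncoordinated beating. Degenerate faces (area < 1e-9 µm²) are
excluded and flagged, never imputed.

## Cross-stage concatenation and the fate map

Anatomical correspondence across stages is built by chaining: a
reference point cloud ("eye-PC", one specimen's SurfaceMap) is carried
over each stage transition by a "hook" specimen whose own motion links
its SurfaceMaps at the two stages. Each eye point inherits the
displacement of its nearest hook node (position plus displacement, not
the raw node position, so the hook's point density does not quantize the
result). Because both SurfaceMaps of a stage already share the Atlas
frame, the default chain step is direct nearest-neighbour matching; the
full re-alignment (t-mixture + mask morph + matching) is available as a
refinement option for SurfaceMaps that disagree more than their node
spacing.

Stepwise deformation is always computed on native Live-Shapes between
the representative frames of consecutive groups, then placed in Atlas
space through the specimen's SurfaceMap. Per reference point, the step
mean over contributing embryos is arithmetic (a geometric mean is
available behind a flag; the quantities are multiplicative, and the two
differ by under 1% at the observed between-embryo spread). Cumulative
growth and anisotropy over an interval of groups are the products of the
step means; the products are exactly associative over interval splits,
and points lacking a contributor at any step are excluded rather than
imputed — imputation would fabricate mechanics.

The Dynamic Atlas carries one reference cloud through a single
most-complete specimen path (one hook per transition, maximal coverage
by default, user-overridable) and supports pseudo-cell tracking: seeds
snap to the nearest reference point (default snap radius: median
inter-node spacing) and follow its per-stage positions. Trajectory
continuity is enforced with two rules — no point may jump more than 5×
the median jump (plus a node-spacing floor), and the median jump itself
may not exceed 5× the node spacing — which catches a wrong-stage hook
spliced into the path. Zone-growth validation partitions the reference
faces into zones (default: 10 equal-count bins along the first principal
axis), sums face areas per zone per stage, smooths each profile across
stages with a least-squares degree-3 B-spline, and scores two profiles
by per-stage rank agreement (default tolerance ±1 rank, configurable and
recorded; border zones can be excluded).

## The synthetic ground truth

The generator emulates the data regime the pipeline is built for, with
closed-form ground truth. The surface family is a crescent-like open
cylinder sheet over material coordinates (u, v) ∈ [0,1]²:

    S(u,v,t) = c + [ (u−½)L(t),  r(u,t) sin a,  −r(u,t) cos a + β t sin(πu) ]
    a = (v−½)φ(t)

with axial elongation L(t) = L₀(1+0.5t) (L₀ = 32 µm), radial growth and
a mid-tube bulge r(u,t) = r₀(1+0.2t)(1+0.2t sin πu)(1+0.15(u−½))
(r₀ = 10 µm), circumferential closing φ: 1.1π → 1.85π, and a progressive
mid-tube bend β = 8 µm. The taper (axial asymmetry) and the bend are
biologically motivated — real heart tubes are fore-aft asymmetric and
loop progressively — and they are also what makes rigid alignment
well-posed: a fore-aft symmetric shape leaves a proper end-for-end flip
free, and a straight nearly closed tube is nearly rotationally symmetric
about its axis, so either degeneracy would let a geometrically perfect
alignment scramble the material correspondence.

Because material points are identified by (u, v), the flow map between
any two times is exact, and so are per-face deformations: the surface
map t₀→t₁ has metric pullback C = G₀⁻¹G₁ (G the first fundamental
form, computed from exact partials), whose eigenvalue square roots are
the principal stretches; J is their product. The discrete per-face J
converges to this analytic value under mesh refinement (property-tested:
error at least halves when the mesh step halves).

Rendering: membrane-shell intensity exp(−d²/2σ²) from the distance to
the surface (σ = 1.2 µm), Gaussian blobs at cell anchors advected by the
flow (80 cells of radius 3 µm — the synthetic "cell diameter" is 6 µm),
additive Gaussian noise (σ = 0.03), exponential bleaching (rate
0.02/frame), 64³ volume at 1 µm isotropic voxels, 8 frames over the unit
pseudo-time (15 simulated minutes per frame). A "mixing" mode adds
random tangential walks to the cells while the membrane flows coherently
— the negative control under which Lagrangian propagation must degrade,
asserted as an error-growth-slope ratio > 2 rather than as a specific
number, which is data-dependent.

Cohorts fragment the timeline into per-specimen windows of 2–3 stage
transitions (staggered with one-stage overlaps so every transition is
covered; window sizes are forced longer when the specimen budget
demands it), each under a uniformly random rigid pose about the shape
center, a ±5% perturbation of the growth parameters, and with both tube
ends cut at 15% of the axial extent (the routinely missing inflow and
outflow tracts). Frames sit exactly on the stage times, mirroring a
staging system in which each group has one representative frame.

What the generator does not emulate: optics beyond Gaussian blur (no
PSF anisotropy, no depth attenuation), segmentation error (masks and
meshes derive from the analytic surface), cell divisions, and
between-embryo variability beyond smooth parameter jitter. Passing the
acceptance suite therefore demonstrates the pipeline's internal
consistency and its robustness to fragmentation, pose, density mismatch
and missing regions — not robustness to segmentation noise or optical
artifacts in real data.

## Problem sizes and test design

The test suite regenerates all data at run time. The motion-estimation
check uses the 64³/8-frame rendered scene and registers it twice
(midpoint-anchored and frame-0-anchored, about a minute each); the
integration round trip uses a 6-specimen cohort over 8 stages with
~16 Atlas projections at 2 µm mask pitch (a few minutes). These sizes
were chosen as the smallest at which the checked effects (sub-cell
tracking error, error halving by midpoint anchoring, 10%-accurate
cumulative growth, 95% of pseudo-cell fates within two cell diameters)
are cleanly resolved above discretization noise.

## Known limitations

* The FFD optimizer (L-BFGS-B per level) is one reasonable choice for
  the stated four-level hierarchy; only its outcomes (ground-truth flow
  recovery) are pinned by tests, not its trajectory.
* The t-mixture component count (half the source nodes) follows the
  pipeline's convention; it was not re-tuned.
* `mesh_to_mask`'s inside test assumes the nearest-surface-sample normal
  is informative; extremely thin folded geometry could confuse it.
* Rank-agreement scoring of growth profiles exposes its tolerance
  parameters instead of hard-coding one "accuracy" number; the published
  kind of summary depends on choices the source data do not pin down.
* Wall-clock times are logged for information only and never asserted.
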