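# Methods

`bonemorph` reimplements a combined internal/external analysis of an
ontogenetic bone series: whole-bone trabecular morphometry of microCT
volumes together with sliding-semilandmark geometric morphometrics of the
external surface, and canonical-pointcloud statistics for mapping where
two age groups differ. Real juvenile microCT series are rarely shareable,
so the package carries its own ground-truthed phantom generators; every
stage is validated by parameter recovery against those truths rather than
against any particular specimen collection. This note records the models,
the defaults that matter, the numerical choices, and what the phantoms do
and do not establish about real data.

## Phantoms (what the synthetic data emulates)

**Trabecular structure.** Two families stand in for trabecular bone:
periodic plate/rod lattices, whose bone volume fraction, strut thickness
and spacing are analytic (plates: BV/TV = t/(t+s)); and thresholded
Gaussian random fields, where white noise is smoothed (base sigma
3 voxels) and cut at the quantile realizing a target BV/TV. Anisotropy of
the Gaussian family is induced before thresholding by per-axis smoothing
stretch; its exact degree of anisotropy has no closed form, so its truth
is the dominant axis plus measured MIL values, not an analytic DA.
Phantoms use 0.05 mm voxels at 64–128 voxels per axis — coarser than
research microCT (12–38 µm) but in the same resolution regime of ≥4
voxels per trabecula that the morphometric estimators assume.

**Imaging.** A solid cortical shell of constant thickness is laid on the
inside of an ellipsoidal envelope (constant thickness enforced with a
Euclidean distance transform); phases (air / bone / optional sediment
blobs) map to configurable gray means, followed by Gaussian PSF blur and
additive Gaussian noise. SNR is defined as half the bone–air contrast
over the noise SD. No beam hardening, ring artifacts or scanner-specific
noise are simulated; a segmentation Dice achieved here bounds performance
on clean data only.

**Ontogenetic landmark series.** Configurations are built as
`CS · (mean + A·ln CS + ε)`: a fixed mean configuration (a well-spread
point set on an ellipsoid), a seed-reproducible unit allometric
displacement field `A` scaled by the allometric slope, isotropic Gaussian
landmark noise ε, and a per-specimen centroid size CS drawn per age
class. The four classes follow the emulated study design
(12 / 25 / 21 / 12 specimens; ages 0–1, 1.1–3, 3.1–6, 6.1–10 years).
Defaults: class CS means 20, 26.2, 34.3, 45 mm — evenly spaced in log
size, i.e. a geometric growth schedule consistent with a foot that
reaches about a third of adult length at birth and two thirds by age
three — within-class log-SD 0.12, allometric slope 0.1, landmark noise
0.01 (shape units). The smooth size schedule matters: strongly clustered
sizes make pooled PC1 scores visibly non-normal, and the conditional test
battery would then (correctly) abandon the parametric branch; even under
exact normality the Shapiro gate rejects 5% of replicates by
construction, so parametric-branch detection rates near 95% are the
ceiling.

**Scalar-field ensembles.** Unit-variance smooth Gaussian fields on a
ball lattice (spacing 1 unit, radius 8 by default), generated by
smoothing white noise on an enclosing grid to a stated FWHM and sampling
at the lattice. A group effect is added *after* smoothing, strictly
inside a stated ball, so "outside the effect region" has a sharp meaning
and false positives there are genuinely false.

All generators take one explicit seed and no global RNG state is used;
every phantom plus its truth is bit-reproducible from (spec, seed).

## Segmentation

The windowed two-stage clusterer tiles the volume into overlapping
subvolumes (default 64³, 25% overlap), runs seeded k-means++ on the gray
histogram of each tile to initialize fuzzy C-means (fuzzifier m = 2,
default 3 classes: air, bone, sediment), and blends per-voxel class
memberships across tiles with a strictly positive triangular window, so
the result is independent of tile traversal order. Bone is the class
with the highest mean gray. Gray values are binned (1024 bins) before
clustering — lossless in practice for one intensity feature — and the
feature is range-normalized, making the output invariant to affine
rescaling of the input. Constant tiles are skipped with a warning and
their voxels inherit blended memberships from overlapping neighbours (or
a whole-volume fallback run). A white top-hat prefilter (ball of a
physical radius) is available for poor bone/sediment contrast.

## Compartment separation

Segmented bone is smoothed by opening+closing with a ball element
(diameter 3 voxels by default, escalated to 5 when the shell stays
porous; outside the grid counts as foreground for erosions and background
for dilations so full masks pass unchanged). A perforated shell is
closed by an escalating dilate/erode cycle — cycle *i* applies *i*
dilations then *i* erosions, because repeating a fixed-radius closing is
idempotent — until the exterior background can no longer reach an
enclosed cavity. The outer (periosteal) mask is the flood-filled closed
bone united with the original segmentation. The inner (endosteal) mask
combines two estimates: a morphological closing of the marrow space
(radius 2 voxels), and an erosion of the outer mask by the cortical
thickness read off as a low percentile (default 1%) of the
exterior-distance values over marrow voxels. Closing alone leaves gaps
where struts meet the shell; the distance-based erosion recovers them
(trabecular Dice 0.995 and cortical Dice 0.999 on the noiseless shelled
phantom, versus ~0.93 for closing alone). Cortical bone is then
`bone ∧ (outer − inner)` and trabecular bone `bone ∧ inner`; the mask
algebra (disjointness, nesting, volume conservation) holds by
construction. A mask with no enclosed cavity yields an empty trabecular
compartment with a warning.

## Trabecular morphometry

**Sampling grid.** Spheres (default diameter 5 mm) move along a
background lattice of nodes (default 2.5 mm) clipped to spheres that
reach the inner mask. "5 mm spherical volume" is read as sphere
*diameter*, giving tangent spheres on the 2.5 mm grid. Local BV/TV is
bone voxels over inner-mask voxels in the sphere; spheres that miss the
inner mask return an undefined-sample marker (NaN).

**MIL fabric.** For each of 128 quasi-uniform directions (spherical
Fibonacci hemisphere), a raster of parallel test lines (2 voxels apart)
traverses the sphere. Phase crossings are counted *exactly*: each line's
intersections with interior voxel faces are enumerated analytically and a
crossing registers where the two voxels sharing the pierced face differ
in phase. This makes the estimator consistent with the closed-form
face-count identity (crossings per unit length in direction u equal
`(Nx|ux| + Ny|uy| + Nz|uz|) / V` for the voxelized geometry), which the
test suite uses as an independent 1024-direction oracle; agreement is
within 5% per direction, limited only by the finite line raster.
Naive point-sampled ray marching was rejected: at practical step sizes it
misses double crossings at thin structures and disagrees with the face
identity by 10–40%. The fabric tensor is fit by least squares to the
classical MIL ellipsoid (quadratic form in 1/MIL²); fabric eigenvalues
are `1/sqrt(eig)` sorted descending, and DA = 1 − λ3/λ1. Ideal plates
drive the in-plane quadratic-form eigenvalues to ~0 and fit noise can push
them slightly negative, so eigenvalues are floored at 1e-4 of the largest
(capping DA at 0.99). Directions with zero crossings are excluded; fewer
than 6 usable directions marks the sample undefined.

**Tb.Th / Tb.Sp / Tb.N.** Local thickness is the
maximal-inscribed-sphere (distance-ridge) definition, computed by
sweeping candidate sphere radii from the Euclidean distance map in
descending half-voxel bins; Tb.Th averages it over bone, Tb.Sp over
marrow within the inner mask (the inner-mask boundary acts as a phase
boundary), and Tb.N = 1/(Tb.Th + Tb.Sp). Structures cut by the volume
faces have no enclosing boundary and inflate the average, so callers can
restrict the averaging region (`roi`); the validation phantoms average
away from the open faces. Specimen summaries report mean/SD of DA and
BV/TV (percent) over defined grid samples plus the three global metrics.

## Mesh mapping

The trabecular region is meshed by Delaunay tetrahedralization of an
interior point lattice plus marching-cubes boundary vertices downsampled
to matching density, clipped to tetrahedra whose centroid lies in the
mask; mesh volume tracks the voxel volume within a few percent. Grid
scalars are interpolated to element centroids barycentrically over the
Delaunay triangulation of the sample nodes; centroids outside the sample
hull take the nearest node's value and are flagged (bounded behaviour is
preferable to extrapolation for colormaps). Meshes are written as legacy
ASCII VTK with cell-data arrays (`BVTV`, `DA`), readable by ParaView.

## External shape analysis

**Template.** 228 points: 8 fixed landmarks, 45 curve semilandmarks on 8
curves (9, 3, 9, 3, 6, 6, 5, 4 points, each curve running between its two
named fixed landmarks) and 175 surface semilandmarks. The synthetic
template lives on an ellipsoid with fixed landmarks placed by
farthest-point sampling — a programmatic stand-in for interactive
digitization on a real bone. Templates transfer to a target by a TPS
warp of the 8 fixed landmarks followed by closest-point projection of
the semilandmarks onto the target surface.

**Sliding.** Semilandmarks slide to minimize TPS bending energy (3D
kernel U(r) = −r): per sweep, the bending-energy matrix of the current
reference (template on the first sweep, the recursive Procrustes
consensus thereafter) defines a quadratic form; curve points move along
their polyline tangent and surface points in their tangent plane; the
unconstrained tangent-space minimizer is solved in closed form and the
slid points are reprojected to the surface. Reprojection can raise the
energy, so the step is damped (halved, up to 4 times) until the energy
does not increase — the per-sweep energy trace is non-increasing by
construction and asserted in tests. Fixed landmarks never move.

**GPA, PCA, statistics.** Partial generalized Procrustes: centring,
scaling to unit centroid size, and iterative rotation to the consensus
(no tangent-space projection), with the stored consensus equal to the
mean of the aligned shapes. Shape-space PCA runs on the flattened
Procrustes coordinates, form-space PCA on the same matrix augmented with
ln CS; PC signs are fixed by making the largest-magnitude loading
positive. The conditional battery on the leading PCs: Shapiro and
Levene at α = 0.05 gate ANOVA + Tukey's HSD versus Kruskal–Wallis +
Dunn's test (rank z statistics with tie correction, Holm adjustment —
written in-package because no installed library provides Dunn), plus
Pearson's r of each PC against ln CS. Age-to-class assignment uses the
four locomotor classes with upper bounds 1, 3, 6 and 10 years.

## Canonical-pointcloud comparison

Correspondence points (default 1200) are placed by seeded farthest-point
sampling of a dense surface sample, and matched across specimens by a
rotation search (160 grid rotations scored by nearest-neighbour cost,
refined by ICP) followed by nearest-point matching to the reference —
a deliberate substitution for the published alignment tool, preserving
the downstream contract (corresponding points across specimens) with a
much smaller mechanism. Note the rotation search is only identifiable on
surfaces without rotational symmetry. The specimen closest to the GPA
consensus donates its mesh, which is TPS-warped to the consensus; the
canonical cloud is a lattice at the nominal spacing (default 1.75 mm)
spanning the mean mesh, with boundary-grazing lattice points pulled a
short step inward so the cloud reaches the surface the way uniform
tet-mesh vertices do while keeping nearest-neighbour spacing within 25%
of nominal.

**CPD.** Rigid, affine and Gaussian-kernel deformable Coherent Point
Drift are implemented in-package (EM over a Gaussian mixture with a
uniform outlier component; deformable defaults β = 2 × spacing, λ = 3,
w = 0.1). The reported objective is the true mixture negative
log-likelihood including the Gaussian normalization; an increase across
an EM step beyond numerical tolerance raises an error. With fixed unit
scale the σ² update must use the general quadratic form — the
optimal-scale shortcut is invalid there and produced genuine objective
increases before the fix.

**Scalar transfer and statistics.** Scalars move to the canonical cloud
by barycentric interpolation over the Delaunay triangulation of the
registered source points (nearest-value fallback outside the hull,
flagged). Group maps are per-point mean, SD and CV (computed per group;
zero means flag CV as undefined). Homologous points are compared with a
pooled-variance two-tailed t test — pooled, not Welch, because the
t-field theory assumes a single degrees-of-freedom across the field.

**Multiple-comparison control.** Two corrections, kept deliberately
independent so each can check the other:

* *Random field theory.* Field smoothness is estimated from per-point
  standardized residuals via squared differences over a 6-nearest-
  neighbour graph, inverted under the equivalent-Gaussian-kernel
  convention (a field made by smoothing white noise with kernel sigma has
  autocorrelation `exp(−h²/4σ²)`; FWHM = √(8 ln 2)·σ — using the
  autocorrelation scale here instead of the kernel scale overestimates
  FWHM by ~40%). Resel counts R0–R3 treat the cloud as the ball of
  equivalent volume (`n_points · spacing³`); the two-tailed threshold
  solves expected-Euler-characteristic = α with the standard t-field EC
  densities, and is never below the uncorrected two-tailed threshold
  because R0 = 1 is included. At the low degrees of freedom typical here
  (df ≈ 14–30) RFT is conservative: thresholds run 4–13% above the exact
  permutation thresholds.
* *Permutation.* Max-|t| over group relabelings, exact enumeration when
  fewer distinct relabelings exist than requested permutations, seeded
  otherwise.

Display maps retain only significant t values.

**Power of the planted-effect check.** A 1.5 SD group shift at n = 10
per group has pooled-t noncentrality 1.5/√(2/10) = 3.35, while the exact
FWER-0.05 max-|t| threshold on any realistically smooth cloud of several
hundred points measures 4.4–4.9 — so *no* FWER-controlling procedure can
flag half of the effect points at that design size (≈20% is attainable).
The recovery simulations therefore use n = 16 per group (noncentrality
4.24) on fields of FWHM 5 lattice units, where RFT sensitivity measures
≈0.5 with out-region FWER ≤ 0.05.

## Pipeline

One config (YAML or dict) drives phantom → segmentation → compartments →
metrics → mesh map → geometric morphometrics → group comparison. Each
stage's seed derives from the pipeline seed by hashing the stage name
(kept below 2³¹); the manifest records the config, its hash, package
version, per-stage wall time and SHA-256 of every output, and suffices to
re-execute an identical run — reruns are bit-identical. The bundled demo
runs an 80³ phantom battery in well under a minute; validation problem
sizes throughout (64³–96³ volumes, 20–228 landmarks, 50-replicate
simulations) were chosen so the full validation suite completes in a few
minutes on one CPU while keeping ≥4 voxels per trabecula and ≥2 grid
nodes per sphere diameter.

## Known limitations

* Phantoms are statistical stand-ins, not anatomically realistic bones;
  passing recovery tests demonstrates estimator correctness, not
  performance on scanner data with beam hardening or mummified tissue.
* The MIL estimator measures the voxelized geometry; the voxelization
  itself carries a small axis-aligned bias (isotropic continuum
  structures measure DA ≈ 0.01–0.03 at these resolutions).
* The equivalent-ball resel approximation ignores the true cloud shape;
  together with low-df conservatism, RFT thresholds are mildly
  conservative. The permutation path is exact and preferred when runtime
  allows.
* The rotation-search correspondence assumes shapes without rotational
  symmetry and of broadly similar form; it does not replicate the
  published tool's Procrustes-over-alignments machinery.
* Tb.N uses the identity 1/(Tb.Th + Tb.Sp); the alternative mid-axis
  definition is out of scope.
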