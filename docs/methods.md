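# Methods

This note documents the models implemented in `spheroidkit`, the parameter
conventions, the numerical choices made where the design was open, what the
synthetic phantoms do and do not emulate, and known limitations.

## Coordinate and unit conventions

Arrays are indexed (Z, Y, X), 0-based. All voxel-unit parameters (radii,
thresholds, alpha) are interpreted in the *downscaled* working image
(default 0.65 µm/voxel, from a 0.325 µm lateral pitch and a 0.5 downscale);
micrometre values follow by multiplying with the pitch. Intensities are
min–max normalized to [0, 1] when the working image is prepared, so every
later threshold is relative to the stack's own dynamic range.

## Pre-processing

The Z axis is stretched by `axial_pitch / lateral_pitch` with linear
interpolation between planes — the cheapest scheme consistent with simply
"filling in" missing planes; cubic alternatives change interior values by
well under the noise level at the typical ~4× anisotropy. Downscaling uses
local-mean (block-average) resampling for integer reciprocal factors
(anti-aliased linear resampling otherwise) to suppress aliasing.

## Segmentation

**Local threshold.** `t_local = m_local + γ·t_global`, where `m_local` is
the mean in a 25×25 window of the sectional plane (mirror padding at
borders), `t_global` is the Otsu threshold of the Gaussian-denoised image
(σ = half the filter range of 3 voxels), and γ = 0.25 weights the global
background term. This is the simplest composition in which γ scales only
the background contribution; the form is confined to one function so
alternatives can be swapped. Thresholding runs per sectional plane along
each of the three axes and the three binary stacks are AND-ed. A constant
image has no Otsu threshold and yields an empty mask with a warning.
Enclosed background cavities smaller than 250 voxels (≈ a quarter of a
typical nucleus volume) are filled; the complement is labelled with
6-connectivity and components touching the stack border are never filled.

**Blob detection.** The inverted image is filtered with
`σ^p · ∇²(g_σ * f_i)` at 5 scales uniform in σ. The conventional exponent
p = 3 is the default. Two facts about solid (indicator) blobs matter here
and are asserted in the test suite: with p = 3 the centre response of a
ball of radius r is extremal at **σ = r/√2** and grows linearly with r;
with p = 2 the extremum moves to σ = r/√3 and the response becomes exactly
radius-invariant. The scale range is therefore [r_min, r_max]/√2 for the
default exponent, and `log_norm_power` is exposed for the invariance-exact
alternative. Detection quality is insensitive to the choice because seeds
come from extended maxima (h-maxima at 2 % of the response dynamic range, a
conventional small plateau depth) rather than absolute response values.

**Watershed.** Seeds are the extended maxima, masked to the foreground and
dilated by a radius-2 ball (merging near-duplicate maxima inside one
nucleus), then 26-connected components. Immersion flooding of the inverted
image uses 6-connectivity and deterministic (value, age) ordering, so
results are bit-reproducible; a hand-written priority-flood oracle in the
tests confirms the partition on small instances. Because flooding does not
stop at nucleus borders, the label map is multiplied by the foreground
mask; objects outside [250, 42 500] voxels are dropped and labels
compacted. The upper gate is kept as an opaque constant — it corresponds to
a far larger sphere than a radius-6 nucleus, and is retained for
compatibility rather than derived.

## Evaluation

Ground-truth centroids are matched greedily in ascending index order to the
nearest unmatched segmentation centroid within 12 voxels; the matched
partner leaves the pool, ties at equal distance go to the lower index. The
greedy pass can differ from an optimal assignment on adversarial ties; the
tests compare against `scipy.optimize.linear_sum_assignment` on the
instances where they must agree. Undefined metric denominators yield NaN,
never 0. Rounding to 2 decimals happens only at reporting.

## Geometry

Outlier removal keeps the largest connected component of the proximity
graph at 20 voxels. The alpha complex keeps Delaunay tetrahedra with
circumradius < α (one of the equivalent conventions; it reproduces both
limit behaviours — the convex hull as α → ∞, the point set as α → 0 — and
is the natural one for solid-volume estimation). Volume is the sum of kept
tetra volumes; boundary triangles are faces of exactly one kept
tetrahedron. Depth is the exact minimum point-to-triangle distance to the
boundary mesh (vectorized barycentric clamping, verified against an
exhaustive scalar oracle), not a rasterized distance transform — exact at
any resolution, O(points × triangles). NDS divides by the dataset maximum
depth, so the deepest nucleus defines NDS = 1; normalizing by distance to
the shape centroid was rejected because spheroids are not perfectly
spherical.

## Cell graphs and density

Edges require *strictly* less than the 40-voxel threshold; ties at exactly
the threshold are excluded. Degenerate Delaunay inputs are retried once
with a seeded 10⁻⁶-voxel jitter. The unit volume 65 450 µm³ behind the
cells/u.v. → cells/mm³ conversion is kept as a configurable constant: it
equals a sphere of radius 25 µm, whereas the 40-voxel threshold at
0.65 µm/voxel corresponds to 26 µm (73 622 µm³); the discrepancy is
documented, not resolved.

## Regions and the outer-region thickness

Regions partition NDS into [0, 0.1) surface, [0.1, core_cut) outer and
[core_cut, 1] core, with core_cut 0.75 for medium and 0.5 for large
spheroids. The mean spheroid radius is the NDS normalizer (maximum depth)
in µm, and the outer-region thickness is `core_cut × mean_radius` — the
depth of the outer/core boundary below the surface. Reported µm values
round half away from zero to one decimal.

## RCP null model

Each replicate places the dataset's cell count uniformly inside the alpha
shape as non-overlapping spheres (radius 6 voxels ≈ the median nucleus
radius) by rejection sampling with a seeded generator; 10 000 consecutive
rejections declare packing infeasible, naming the achieved count. Ten
replicates are pooled: per-bin means averaged over replicates, SE across
replicates. Feasibility bound: random sequential addition saturates near
38 % sphere packing, so configurations must stay below ~20 % nuclear volume
fraction — which real spheroids (5×10⁵–10⁶ cells/mm³, ≈ 250-µm³ nuclei) do.

Two desk-scale effects matter when comparing a sparse sample with its RCP
ensemble and are handled explicitly rather than hidden:

- **Edge effect.** A vertex closer to the surface than one graph threshold
  has a truncated neighbourhood ball, so the density profile ramps up over
  the first `threshold / radius` of the NDS axis. At data scale
  (radius ≈ 300 voxels) this zone ends near NDS 0.1 — the familiar surface
  rise; at test scale the graph threshold is scaled with the shape and
  "interior" means beyond that zone.
- **Rind bias.** The alpha shape of an n-point sample under-covers the true
  volume by a boundary rind that shrinks as n grows, making the RCP
  replicates slightly denser than the sample they mirror. Structure
  comparisons therefore first match the overall density scale between the
  real profile and the ensemble and then compare depth structure in SE
  units.

## Dataset-level analyses

PAM (partitioning around medoids, squared Euclidean) runs on z-scored
features — raw cell counts and volumes differ by orders of magnitude. For
n ≤ 20 the medoid set is found by exhaustive search (deterministic and
optimal; 16 datasets is the intended regime), larger n uses BUILD + SWAP.
The volume–cell fit is ordinary least squares with the Pearson correlation
reported.

## Synthetic phantoms

The generator emulates cleared-spheroid stacks: nuclei as non-overlapping
spheres packed in a ball, per-nucleus intensity drawn from [0.55, 1] with a
quadratic radial falloff to 70 % at the rim (heterogeneous staining), a
σ = 1 voxel Gaussian blur standing in for the PSF (producing the
apparently-touching clusters of densely packed data), additive Gaussian
noise (σ = 0.03) over a 0.10 background, and optional Z subsampling to
emulate coarse axial pitch. Defaults state a realistic world: 200 nuclei in
a radius-63-voxel ball give ≈ 7×10⁵ cells/mm³ (mid-range of measured
spheroid densities); radii come from a normal distribution centred at 5.25
voxels (SD 0.75) clipped to the measured [3, 6] range, consistent with a
median nucleus volume near 267 µm³. Layered phantoms thin the core by
1/density_ratio beyond a programmed NDS boundary.

Not emulated: light-sheet optics (shadowing, stripe artifacts, depth-
dependent attenuation), scattering, clearing inhomogeneity, nucleus shape
irregularity beyond spheres, and mitotic figures. A green phantom test
therefore establishes algorithmic correctness at realistic density, size,
contrast and noise — not robustness to optical artifacts.

## Known limitations

- Whole stacks are processed in memory; no tiling or GPU path.
- Alpha shapes assume a dense, roughly uniform centroid cloud; very sparse
  or highly concave aggregates need a different α or model.
- The greedy centroid matcher is order-dependent on exact ties.
- Centroid-distance features use all object voxels (not surface voxels
  only); intensity features are normalized per stack.
- Region cuts (0.1 / 0.75 / 0.5 NDS) are user-supplied by design; the
  change-point in a profile is a judgement call, not an estimator the
  package imposes.
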