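# Methods

This note documents the models, conventions and numerical choices behind
`bonequiv`, and what its synthetic validation does and does not show.

## Problem setting

Two CT protocols image the same four knee bones (distal femur, proximal
tibia, proximal fibula, patella): a cone-beam scanner at 0.30 × 0.30 mm
in-plane resolution and 0.60 mm slice thickness, and a multidetector
reference scanner at 0.49 × 0.49 × 0.625 mm. Each bone is segmented in
both volumes; the question is whether the resulting 3D surface models are
geometrically equivalent — specifically, whether the mean signed surface
distance between them is within a clinically negligible margin.

## Surface extraction

Meshes are extracted from the binary masks with marching cubes (Lewiner
variant, so ambiguous cube configurations are resolved consistently) at
the 0.5 level, after zero-padding the volume by one voxel so anatomy
touching the array boundary still yields a closed surface. Vertex
coordinates are physical: `origin + index × spacing`, with array axis
order (x, y, z) = (column, row, slice). Meshes are oriented so the
divergence-theorem signed volume is positive (outward normals).

No smoothing is applied by default: binary-mask marching cubes is then
fully deterministic, and its enclosed volume is accurate to well under 1%
at these resolutions. The staircase surface does inflate the *area* by
roughly +8–12% independent of resolution and adds ~0.1 mm of surface
roughness; an optional Gaussian pre-filter (`smooth_sigma`, in voxels)
removes both (measured sphere-area error 0.03% at σ = 0.8) for users who
prefer smooth surfaces. Note that the voxelization volume error does not
shrink monotonically as spacing is halved — it oscillates with the phase
of the surface relative to the voxel lattice — so accuracy claims are
stated as bounds, not convergence orders.

## Rigid registration

The moving (cone-beam) mesh is aligned to the fixed (reference) mesh with
iterative closest point:

* **Correspondences** are exact closest points on the fixed *surface*
  (point-to-triangle, KD-tree shortlist over triangle centroids with a
  provably sufficient candidate radius), not nearest vertices — the
  discrepancies of interest are far below the voxel size.
* **Update** is the weighted Kabsch/SVD solution restricted to proper
  rotations; mirror solutions are excluded by sign-correcting the
  smallest singular direction. Collinear point sets raise an error.
* **Initialization** aligns centroids; a principal-axes option with
  four-way sign disambiguation (lowest RMS wins) handles large
  misalignments.
* **Trimming**: by default the pipeline discards the worst 15% of
  correspondences per iteration. This matters because the cone-beam scan
  is axially truncated: its flat field-of-view cut cap has no counterpart
  on the fixed surface, and untrimmed ICP measurably biases the pose
  (up to ~15° on a truncated femur phantom).
* **Subsampling**: the pipeline samples 2000 moving vertices (seeded) per
  registration; accuracy on phantoms is ~0.2° / 0.03 mm, unchanged from
  full-vertex runs.
* **Convergence** is declared when the RMS change between iterations
  falls below the tolerance (default 10⁻⁶ mm, capped at 100 iterations).
  With subsampled, trimmed correspondences the RMS fluctuates at ~10⁻⁵ mm
  indefinitely, so robustness trials use 10⁻⁴ mm — one thousandth of the
  ~0.1 mm discretization noise floor; the stricter default only costs
  extra iterations.

Strictly rigid: no scale, no shear.

## Signed distances and the FROI

Distances are directional, from each retained vertex of the registered
moving mesh to the nearest point of the fixed surface, positive where the
vertex lies *outside* the fixed model (the moving model is "larger").
Inside/outside is decided by the generalized winding number of the closed
fixed surface, computed exactly (sum of signed solid angles, numba
kernel) — robust on thin structures where normal-based tests flip.
Non-watertight targets are rejected unless the angle-weighted
pseudo-normal fallback is requested explicitly. Equidistant-triangle ties
resolve to the lowest triangle index (consequences ≤ 10⁻¹² mm).

The FROI restricts comparison to the axial band covered by both scans:
the intersection of the two meshes' clip-axis extents, shrunk by a 2 mm
margin at each end where the extents disagree by more than 1 mm (i.e.
where at least one mesh was cut by its field of view). This keeps the
flat cut caps and their neighborhoods out of the statistics. The patella
is exempt — it is fully contained in both scans. Limitations: two meshes
cut at the *same* height would not be detected as cut, and the margin
must exceed the cap's axial span under residual tilt (a 30 mm bone at 4°
tilts its cap across ±1 mm; the 2 mm default covers realistic, near-
aligned acquisitions).

## Summaries and statistics

* **Per-bone summaries** use the population standard deviation (÷n) and
  the spread interval μ ± 1.96σ — these describe the distribution of
  per-vertex distances (or of per-subject means at group level), not the
  uncertainty of μ. Report values round half-to-even on the decimal value
  at 2 decimals, extended to 3–4 while the magnitude would round to zero.
* **Normality**: Shapiro–Wilk (Royston AS R94, via scipy, cross-checked
  against an independent R computation) and Kolmogorov–Smirnov against a
  normal with the sample's fitted mean and ddof=1 standard deviation. The
  KS p-value uses the standard parameters-known distribution and is
  therefore anti-conservative for estimated parameters; it is a
  descriptive screen, not a gatekeeper.
* **TOST**: sample (÷(n−1)) standard deviation inside the standard error;
  one-sided p-values from Student t with n − 1 df; the reported interval
  is the 1 − 2α (90%) two-sided t-interval, the standard TOST reporting
  convention. The decision satisfies the triple equivalence: both
  one-sided rejections ⇔ max p < α ⇔ 90% CI ⊂ (−Δ, +Δ).
* **Pooling**: all bones of a subject enter one group sample, ignoring
  within-subject correlation; group p-values should be read with that
  caveat. No multiple-testing correction is applied across the two
  groups.
* **Power analysis** is interpreted as a two-sided one-sample t test:
  power from the noncentral t distribution with noncentrality d·√n,
  minimum n found by integer search (d = 0.5, α = 0.05, power 0.80
  → n = 34).

## The phantom generator

Phantoms exist to exercise the pipeline against known ground truth; they
emulate exactly four properties of real paired scans and nothing else:

* **Closed, asymmetric, bone-scale shapes**: analytic primitives
  (capsules, ellipsoids, spheres) blended with a polynomial smooth
  minimum, plus three random bumps so rigid registration is well posed
  (a symmetric shape has a rotation gauge freedom). Joint features
  (condyles, plateau, fibular head) sit at the +z end. Default
  characteristic sizes — femur 30, tibia 26, fibula 20, patella 12 mm —
  are desk-scale: large enough for hundreds of voxels per axis at the
  protocol spacings, small enough that a 16-pair study runs in minutes on
  one CPU. The fibula shaft radius is kept ≥ 5 reference-grid voxels;
  thinner rods show systematic voxelization erosion that would confound
  offset recovery.
* **Systematic offset** δ: grid B is voxelized from the surface offset by
  −δ (signed-distance shift), so a positive δ means modality A's model is
  larger and the pipeline's A→B mean distance should recover +δ.
* **Surface noise**: a fixed-seed sum of 64 Gaussian lobes added to the
  signed-distance value, normalized to zero mean and std σ_noise over a
  thin shell around the surface (normalizing over the bounding box
  instead leaks a random per-pair mean offset of several hundredths of a
  millimetre, which would masquerade as a modality difference). Default
  σ_noise = 0.1 mm, the order of the segmentation-difference spread seen
  in practice.
* **Field-of-view mismatch**: grid A's axial extent is 200/376 of the
  bone's (the ratio of the two protocols' scan heights), cutting the
  shaft end of the long bones; the patella is never cut. Default true
  misalignments are 1–4° and ≤ 3 mm per axis — paired scans are acquired
  near-aligned.

Voxelization classifies voxel *centers* against the signed distance
(no partial volume), matching binary-mask inputs. Identical specs
(including seeds) produce bit-identical grids.

**What phantom results do not show**: anatomical realism, CT physics
(noise texture, beam hardening, reconstruction kernels), segmentation
behavior at thin or ambiguous anatomy, or inter-observer variability.
Passing recovery tests means the *pipeline* is unbiased at the stated
scales; it says nothing about scanner image quality.

Known metrological bias: between two staircase (unsmoothed) meshes, the
nearest-point distance systematically attenuates a true offset by a few
hundredths of a millimetre (the nearest point on a rough surface is
closer than the mean surface), the dominant term in the measured
end-to-end recovery error (RMSE ≈ 0.03 mm at |δ| ≤ 0.3 mm).

## Fixture-based reproduction

The packaged table (`data/bone_means.csv`, checksum-guarded) carries the
per-bone mean distances of the reference cohorts: 16 patient, 40
single-knee cadaver and 40 bilateral-knee cadaver values, printed to 2–3
decimals. Statistics recomputed from it match the published values to
printed precision, with one caveat: the published KS D (0.0938 for the
pooled patient + single-knee group) was evidently computed on unrounded
means, and the 2-dp rounding perturbs D by up to ~±0.01; the fixture
reproduces D ≈ 0.100. The Shapiro–Wilk W, group means, and TOST interval
bounds are insensitive to the rounding at the reported precision.

## Problem sizes used in validation

The test suite and examples run phantoms at the default desk-scale sizes
above, 16-pair studies for end-to-end recovery, 50 coarse-grid trials for
registration robustness, and 10³–5·10³ replicate simulations for the TOST
operating characteristics; all statistical acceptance quantities are
exact recomputations from the fixture.
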