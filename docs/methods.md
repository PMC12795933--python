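# Methods

This note documents the models and numerical choices behind `surfnav`: what
the synthetic studies simulate, which parameters matter, and what passing
results do and do not establish about real operating-room data.

## The navigation problem

A biopsy trajectory is planned on a preoperative head scan as an entry point
on the skin and a target point at depth. During surgery the plan must be
mapped onto the patient. Marker-based systems do this with tracked pointers
and reflective spheres; the markerless approach implemented here aligns the
skin surface extracted from the scan to the point cloud observed by a
head-mounted depth sensor, with no manual initialization. Navigation error is
quantified by the **off-plan distance**: the shortest Euclidean distance from
the probe tip to the *infinite line* through the planned entry and target
points. The line (rather than the entry–target segment) is the primary
definition because a navigation readout penalizes lateral deviation from the
planned axis, not position along it; a segment variant exists behind
`mode="segment"` for comparison.

## Digital head phantom

The phantom replaces both a 3D-printed head and patients. It is an icosphere
scaled to head extents (155 × 195 × 225 mm; +x right, +y anterior,
+z superior) with radial Gaussian relief for the nose, brow, chin,
cheekbones, eye sockets and occiput, plus eight seeded low-amplitude bumps
that break left–right symmetry. Facial relief is what makes markerless
surface registration well-posed, so its amplitude (`feature_amplitude_mm`,
default 15 mm) is a first-class parameter. After relief the mesh is rescaled
per axis so the bounding box equals the requested extents exactly. Everything
is deterministic in the spec's seed.

Fifty-one conical fiducials are placed by farthest-point sampling over the
face and scalp (minimum spacing 15 mm; the bottom 18% of the head is
excluded as the neck/underside). Each cone apex lies 20 mm below its surface
centre along the inward normal; candidates whose apex would come closer than
96% of that depth to any part of the surface (possible under high-curvature
relief) are rejected. The planned trajectory of a fiducial runs from the
surface opening to the apex. The physical cone's 0.2 mm probe margin is
carried as `cone_margin_mm` for completeness; it does not enter the
simulated geometry.

Voxelization uses a column-parity fill (crossing counts along z per (x, y)
column), which is exact for watertight meshes, with configurable voxel size
(0.5 mm isotropic by default, matching a T1 protocol; an anisotropic
1.0 × 0.5 × 0.5 mm CT-style grid is supported), two-valued intensities
(inside 100, outside 0) and optional Gaussian intensity noise (SD 5) — only
threshold separability matters downstream.

**Skin shift** is modelled as a sum of at most five Gaussian radial-basis
bumps (centres drawn uniformly on the surface, directions random, widths
40–70 mm) whose magnitude is multiplied by a smoothstep ramp along the
anterior–posterior axis (anterior weight 0.3, posterior 1.0) and clamped to
`max_magnitude_mm`. This mirrors the clinical observation that positioning
deforms the skin more towards the back of the head. The broad widths are
deliberate: the field must displace the *visible* face a little and the
posterior scalp a lot for the regional error gradient to emerge.

## Surface extraction

Thresholding keeps voxels at or above `tau` (default 50, between the two
phantom intensities) and then the largest 26-connected component. Median
smoothing converts the 3 mm window to an odd voxel count per axis (nearest
odd, minimum 3) and takes an exact majority vote — an odd window can never
tie. Before meshing, internal cavities are flood-filled so the surface bounds
a solid; marching cubes runs at the 0.5 iso-level of the box-smoothed binary
field (3-voxel window), which removes voxel staircasing — without it a
sphere's extracted area overshoots the analytic value by ~50% at these
resolutions; with it the error is ~1%. Decimation is a quadric-error-metric
edge collapser (area-weighted face quadrics, optimal-position solve with
midpoint/endpoint fallback, collapses that would flip a face normal are
rejected), with the 100 000-triangle default of the clinical processing
chain. Reference models are cropped from landmarks the generator records:
`face_only` keeps the surface anterior to the coronal plane through the head
centre; both modes remove 15 mm spheres around the eyes.

## Depth sensor

The simulated sensor is a 320 × 288 pinhole camera with a 75° horizontal
field of view (loosely modelled on a mixed-reality headset's depth camera;
all intrinsics configurable), rendered by a perspective-correct z-buffer
rasterizer (depth = camera-z of the first hit at the pixel-centre ray;
misses are 0). Noise is applied along the viewing ray only — axial Gaussian
jitter (SD 1 mm), then 0.25 mm range quantization, then 5% Bernoulli
dropout — the dominant error structure of time-of-flight sensors; lateral
jitter is a known omission. A coverage metric (fraction of reference area
visible from the camera) labels partial-view scenarios.

## Registration

Both clouds are voxel-downsampled to 4 mm; normals come from the smallest
eigenvector of the 30-neighbour covariance (scene normals oriented to the
sensor origin, model normals sign-matched to the sampled face normals). FPFH
descriptors use an 11-bin histogram per Darboux angle (33 bins total,
blocks normalised to percentage mass) over a 20 mm radius — five times the
downsampling voxel. Matching is mutual nearest neighbour in descriptor
space, capped at the 1200 best pairs; a smaller cap (250) was observed to
keep mostly flat-region matches, whose descriptors are close yet
uninformative, and to permit 180° face/occiput flips with the full-head
reference.

The global stage follows the decoupled truncated-least-squares scheme with
scale fixed at 1 (rigid same-patient anatomy): correspondences are pruned to
the maximum clique of the compatibility graph (edge iff the source and
target pairwise distances agree within twice the noise bound, default
2 × 4 mm); rotation is solved on translation-invariant measurement pairs
(all pairs within the clique, capped at 2000) by graduated non-convexity
over a truncated-least-squares cost, annealing the surrogate by a factor
1.4 per outer iteration from a near-convex start set by the largest initial
residual; translation is solved per component by adaptive interval voting
(consensus of ±noise-bound intervals, then the consensus mean). With clean
correspondences the weights never truncate and the result reduces exactly to
the closed-form SVD alignment. The clique solver is an in-house
branch-and-bound with a greedy-coloring bound, preceded by a multi-start
greedy lower bound and k-core reduction, and capped by a work budget
(~5 × 10⁵ coloring operations; the search is also skipped when the greedy
clique already exceeds 60 nodes). Past the cap the best clique found is
used: the downstream robust stages tolerate the few residual outliers this
may admit, and the cap keeps worst-case runtime bounded on the dense
compatibility graphs that noiseless or highly symmetric scenes produce.

ICP refines from the global estimate: nearest-neighbour correspondences
within 10 mm (ties to the lowest index), point-to-plane updates by a
linearised 6-DOF solve (point-to-point via closed-form SVD is available and
carries the classical guarantee that the correspondence-stage RMSE never
increases), convergence at relative RMSE change below 1e-6 or 50
iterations. The final verdict — the numeric stand-in for a surgeon's visual
check of the overlay — declares success iff inlier RMSE ≤ 3 mm *and* at
least 30% of the model points find a scene point within 10 mm. A scene
covering under ~10% of the face fails this overlap gate.

## Study harnesses

**Accuracy sweep.** `perturb_to_accuracy` composes the true registration
with a random small rotation (about the surface-sample centroid) plus
translation, scaled by bisection so the mean surface displacement equals the
requested within-system accuracy to better than 0.1%. For each accuracy in
{0.5, …, 2.5} mm and each of three repeats one perturbed registration is
drawn; every planned entry point is mapped through it and measured with an
isotropic probe-placement jitter (SD 0.5 mm, the freehand-pointer error; an
optional entry-placement jitter exists and is off by default). 5 × 51 × 3 =
765 records; the summary reports per-level mean ± SD and the Spearman rank
correlation (average ranks, large-sample p).

**Patient-style study.** One phantom per subject (24 fiducials at the
study's working resolution), a trajectory in the subject's assigned head
region (frontal/temporal/posterior by the angle from the anterior axis, with
the crown falling in the middle band), skin shift applied to the live
surface only (the planned trajectory inside the head stays rigid), a random
rigid patient pose (≤ 20°/100 mm), frontal depth view, sensor noise, then
the full pipeline with the face-only reference and exactly one full-head
retry on failure. The probe tip is taken as the projection of the overlaid
entry onto the live (shifted) skin — the pointer is physically held on the
patient — so posterior skin displacement enters the posterior off-plan
directly, while rotational registration error additionally grows with the
lever arm from the registered facial surface.

**Pose-recovery benchmark.** Twenty seeded scenes (default phantom, frontal
render, noise SD 1 mm, 5% dropout, random pose ≤ 30°/100 mm) report
success, rotation/translation error against the generating transform and the
mapped-entry error at a frontal fiducial.

## Problem sizes and determinism

The default phantom uses a 10 242-vertex icosphere (20 480 faces), the
pipeline samples 8000 model points, and study harnesses run 20-scene /
21-subject batches; these sizes make a full registration take a few seconds
and keep whole studies in the minutes range while leaving every phenomenon
of interest measurable. All randomness flows from a single master seed
through `numpy.random.default_rng`; fixed seeds reproduce phantoms, fields,
studies and result files bit for bit.

## Limitations

The phantom is smooth and rigid apart from the modelled skin shift: no hair
(which degrades scalp returns in practice), no facial expression change, no
specular or multi-path sensor artifacts, no sensor-pose drift, and lateral
depth noise is omitted. The success verdict's thresholds (3 mm RMSE, 0.3
overlap) replace a human judgement and were chosen for testability, not
clinical validation. Passing the synthetic studies therefore demonstrates
the *algorithmic* soundness of the chain — robust global alignment, ICP
convergence, correct error accounting, the expected direction of the
accuracy trend and of the posterior error gradient — not clinical accuracy
on real patients, where the physical error budget (pointer calibration,
display latency, tissue compressibility) is outside this package's scope.
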