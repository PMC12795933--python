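# surfnav

Markerless, surface-based surgical navigation, end to end and in silico.

Image-guided neurosurgical biopsies require registering a preoperative head
scan to the patient on the table. Conventional frameless navigation does this
with reflective markers and a tracked pointer traced over the skin — a setup
that takes many minutes and whose *reported* registration accuracy understates
the true error at the target. An emerging alternative skips markers entirely:
a head-mounted depth sensor observes the live 3-D landscape of the patient's
face, and the skin surface extracted from the preoperative scan is aligned to
that point cloud fully automatically.

`surfnav` implements and evaluates that pipeline for researchers in
image-guided intervention:

- **phantom** — seeded synthesis of digital head phantoms: a watertight,
  head-shaped surface with procedural facial relief, 51 conical fiducials
  whose apices sit 20 mm below the skin, planned biopsy trajectories
  (surface opening → cone apex), voxelized scan volumes, and a smooth
  posterior-weighted "skin shift" deformation model.
- **surface** — the preoperative chain: threshold segmentation (largest
  26-connected component), 3 mm median smoothing, cavity filling, marching
  cubes, quadric-error-metric decimation to 100 000 triangles, and the two
  registration reference models (face-only vs. full head, eyes excluded).
- **depthsim** — a simulated head-mounted depth sensor: z-buffer depth
  rendering from a 320×288, 75° pinhole camera, back-projection to a world
  point cloud, and a time-of-flight noise model (axial jitter, range
  quantization, dropout).
- **registration** — the core method: voxel downsampling → covariance
  normals → 33-bin FPFH descriptors → mutual-nearest-neighbour matching →
  robust global alignment in the truncated-least-squares style (maximal
  clique on the distance-compatibility graph, rotation by graduated
  non-convexity, translation by component-wise adaptive voting) → ICP
  refinement → a numeric success verdict.
- **evaluation** — the two study designs: a 51-point sweep over controlled
  registration accuracies (0.5–2.5 mm, three repeats each) measuring the
  *off-plan distance*, and a patient-style study with skin shift, head-region
  analysis and a full-head fallback model.

## The error metric

For a planned trajectory with entry point $e$ and target $t$ the off-plan
distance of a probe tip $p$ is the perpendicular distance to the infinite
trajectory line:

$$d_{\mathrm{offplan}}(p) = \left\| (p - e) - \big((p-e)\cdot \hat{d}\big)\,\hat{d} \right\|, \qquad \hat d = \frac{t-e}{\|t-e\|}.$$

The robust global stage estimates the rigid map $(R, \tau)$ from putative
correspondences $(s_i, d_i)$ by truncated least squares,
$\min_{R,\tau}\sum_i \min\!\big(\|d_i - Rs_i - \tau\|^2,\, c^2\big)$, solved
in decoupled stages (scale fixed at 1 for rigid anatomy) with graduated
non-convexity for the rotation.

## Worked example

```python
import surfnav as sn

spec = sn.PhantomSpec(seed=42)
head = sn.generate_head_phantom(spec)
fiducials = sn.place_fiducials(head, spec)
trajectories = sn.plan_trajectories(fiducials)
print(f"phantom: {len(head.vertices)} vertices, {len(fiducials)} fiducials, "
      f"trajectory length {trajectories[0].length_mm:.1f} mm")

scenes = sn.run_recovery_study(n_scenes=3, seed=42)
for s in scenes:
    print(f"scene {s['scene']}: success={s['success']}  "
          f"rot={s['rotation_error_deg']:.3f} deg  "
          f"trans={s['translation_error_mm']:.3f} mm  "
          f"entry={s['entry_error_mm']:.3f} mm")

records = sn.run_phantom_study(head, trajectories, seed=42)
summary = sn.summarize(records)
print(f"phantom sweep: {len(records)} records, "
      f"Spearman rho={summary.spearman_rho:.3f} (p={summary.spearman_p:.1e})")
print(summary.per_level.round(2))
```

prints

```
phantom: 10242 vertices, 51 fiducials, trajectory length 20.0 mm
scene 0: success=True  rot=0.094 deg  trans=0.142 mm  entry=0.175 mm
scene 1: success=True  rot=0.027 deg  trans=0.100 mm  entry=0.115 mm
scene 2: success=True  rot=0.283 deg  trans=0.405 mm  entry=0.521 mm
phantom sweep: 765 records, Spearman rho=0.583 (p=7.7e-71)
                       mean   std  count
requested_accuracy_mm
0.5                    0.75  0.41    153
1.0                    1.03  0.50    153
1.5                    1.42  0.74    153
2.0                    1.85  0.92    153
2.5                    2.16  0.91    153
```

The three scenes are noisy frontal depth views (axial noise SD 1 mm, 5%
dropout) of the head posed by a random rigid transform of up to 30° / 100 mm;
the markerless pipeline recovers the pose to a fraction of a degree and
millimetre, so the overlaid entry point lands well under a millimetre from
its true position. The sweep table shows how the measured off-plan distance
grows with the accuracy of the injected registration (765 = 5 levels × 51
points × 3 repeats), with a clearly positive rank correlation.

A thin CLI wraps the same functions
(`surfnav phantom | extract | simulate-depth | register | evaluate-phantom |
evaluate-patient`); every subcommand honours `--seed`/`--config` and writes
JSON stamped with the resolved configuration hash.

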