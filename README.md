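# hybridsurf

Hybrid surface reconstruction for binary MR segmentations: a
Marching-Cubes/Flying-Edges mesh and an MPU-implicit mesh are compared
triangle by triangle against the segmentation boundary, the locally closer
triangles are kept and merged, and an MPU implicit refit to the merged
points yields the final surface — smooth like an implicit model, accurate
like marching cubes.

Intended users: people turning segmented medical volumes (NIfTI/NRRD masks,
or per-slice contour stacks) into quality surface meshes, and people who
need the matching evaluation toolbox (distance statistics, Hausdorff
distance, mean-curvature analysis).

## Method in brief

Three reconstruction paths share one mesh representation:

- **fe** — Marching Cubes organized as the Flying-Edges passes (edge
  classification with per-row trim intervals, pre-counted allocation),
  followed by Taubin λ/μ smoothing to remove voxel staircase artifacts.
- **mpu** — a Multi-level Partition of Unity implicit: an octree of local
  quadric fits to the oriented boundary-voxel cloud, refined wherever the
  local fit error exceeds a tolerance `tol`, blended by compactly supported
  C¹ weights, then polygonized at its zero level set.
- **hybrid** — for each MPU triangle, the nearest FE triangle (by centroid)
  and the nearest segmentation boundary point *P* are found, and the
  triangle with the smaller centroid distance wins:

  δ(T_MPU, P, T_FE) = min(‖C_MPU − P‖, ‖C_FE − P‖)

  The winners' vertices are welded into one oriented point cloud (normals
  recovered from the source meshes) and an MPU implicit is refit with a
  small tolerance (default ¼ voxel) to produce the final mesh.

Evaluation follows the segmentation-distance convention: per-boundary-point
distance to the nearest point **on** the mesh surface (exact point-triangle
projection), summarized as Min / Max / St dev / Mean / % < 0.5 mm
/ % < 1.0 mm, plus symmetric Hausdorff distance on sampled point sets and
per-vertex mean-curvature magnitude via the cotangent Laplacian.

See `docs/methods.md` for conventions, parameter defaults and limitations.

## Worked example

```sh
hybridsurf synth --shape sphere --out sphere.nii.gz
hybridsurf reconstruct --mask sphere.nii.gz --method hybrid \
    --out sphere_hybrid.ply --report report.json
hybridsurf evaluate --mask sphere.nii.gz --mesh sphere_hybrid.ply \
    --out eval.json --colormap dist.ply
```

The same run from Python, comparing all three methods on the bundled
r = 10 mm sphere phantom (1 mm voxels):

```python
from hybridsurf import phantom_suite, hybrid_reconstruct, absolute_distance

name, vol, sdf = phantom_suite()[0]          # sphere
res = hybrid_reconstruct(vol)
for label, mesh in [("fe", res.fe_mesh), ("mpu", res.mpu_mesh),
                    ("hybrid", res.mesh)]:
    _, rep = absolute_distance(res.seg_points, mesh)
    print(label, rep.to_csv_row()[1])
```

prints (mm):

```
fe     0.0992,0.8159,0.1915,0.4066,62.09,100.00
mpu    0.0044,0.4146,0.1300,0.1978,100.00,100.00
hybrid 0.0002,0.5016,0.1319,0.1748,99.90,100.00
```

Columns are Min, Max, St dev, Mean, % < 0.5, % < 1.0.  The smoothed
marching-cubes mesh sits a mean 0.41 mm from the segmentation boundary (the
smoothing pulled it inward), the implicit mesh 0.20 mm, and the hybrid
0.17 mm — below both inputs, because it keeps whichever triangle is locally
closer (here 86% of triangles came from the MPU side, per
`res.report["stages"]["match"]`).

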