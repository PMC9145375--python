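# stairsmooth

Smoothing and validation toolkit for **stair-stepped surface meshes** from
anisotropic medical segmentations — the terraced 3D models you get when a
small, high-curvature structure (a carpal bone, say) is segmented on
thick-slice MRI and the binary mask is stacked into a surface without any
post-processing.

Smoothing such a model is a trade-off: diffusion removes the slab terraces
but also shrinks the enclosed volume and erodes anatomical ridges and
facets, which matters when the object is only ~10³ mm³ to begin with.
`stairsmooth` implements five classical smoothing algorithms behind one
iteration driver, plus the quantitative metrics used to judge that
trade-off, plus synthetic bone-like phantoms so the whole pipeline can be
exercised and tested without any patient data.

## Methods

All methods update every vertex simultaneously by the explicit rule
`p_i ← p_i + λ·U(p_i)` and differ in the local operator `U` over the
one-ring neighbourhood `N₁(i)`:

| id | name | operator `U(p_i)` |
|----|------|-------------------|
| M1 | `laplacian` | umbrella: `(1/m) Σ q_j − p_i` |
| M2 | `predilate` | M1 preceded by a normal-direction dilation inflating the volume by a set fraction; stops when the volume returns to within a threshold of the original, on first contact with the original surface, or at an iteration cap |
| M3 | `scaledep` | scale-dependent umbrella: `(2/E) Σ (p_j − p_i)/|e_ij|`, `E = Σ |e_ij|` |
| M4 | `curvflow` | mean-curvature flow via the cotangent formula `−κ̄n = (1/4A) Σ (cot α_j + cot β_j)(p_j − p_i)`, normalised-explicit or backward-Euler implicit `(I − λ·dt·K) Pⁿ⁺¹ = Pⁿ` |
| M5 | `invdist` | umbrella with inverse-distance weights `ω_j = 1/‖p_i − q_j‖`, normalised |

Validation metrics: signed **Relative Volume Difference**
`RVD = (V_S − V_G)/V_G · 100` (%, negative = shrinkage) and the
vertex-sampled symmetric **Hausdorff distance**
`HD = max(max_x d(x,S), max_y d(y,G))` (mm, exact point-to-triangle
distances), with per-vertex distance fields exportable as
scalar-carrying PLY + CSV heat maps.

## Worked example

```
$ stairsmooth phantom --shape ridged-blob --seed 1 --out-mesh bone.stl
phantom: 1405 voxels, voxel-count volume 702.500 mm^3, analytic volume 697.166 mm^3

$ stairsmooth smooth bone.stl smoothed.stl --method scaledep
M3: 30 iterations, terminated by iterations; volume 702.500 -> 518.938 mm^3

$ stairsmooth evaluate bone.stl smoothed.stl --out report.json
```

The phantom is a lobed, bone-sized blob (~700 mm³) voxelised at
0.5 × 0.5 × 2.0 mm — fine in-plane, coarse through-plane — so its
`voxel-faces` surface shows the characteristic 2 mm slab terraces.  The
report for the scale-dependent Laplacian after the default 30 iterations
reads:

```json
{
  "volume_ground_mm3": 702.5,
  "volume_smoothed_mm3": 518.9376198682488,
  "rvd_percent": -26.129876175338246,
  "hausdorff_mm": 1.4882500318697043,
  "mean_mm": 0.5014673858384814
}
```

i.e. the smoothed model lost 26.1 % of its volume and its worst surface
deviation is 1.49 mm — on an object this small and this coarsely sliced,
30 diffusion iterations are far from harmless, which is exactly the
effect the toolkit is built to quantify.  `stairsmooth compare bone.stl
--out table.csv` runs all five methods and tabulates RVD/HD per method;
`--heatmap` on `evaluate` writes the per-vertex distance field for
inspection in any PLY viewer.

Every run writes a JSON manifest echoing the full effective
configuration, the per-iteration volume log and the termination reason,
so results are reproducible bit-for-bit.

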