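# Methods

## Problem setting

Binary segmentations of small bones acquired with anisotropic voxels
(fine in-plane, coarse through-plane) yield surface models with slab-wise
stair steps.  Smoothing them is a controlled trade-off between surface
quality and fidelity: every diffusion-type smoother shrinks enclosed
volume and rounds genuine anatomical ridges.  The toolkit implements five
standard smoothers and the metrics to quantify that trade-off, and ships
a phantom generator so every claim is testable on synthetic data with
known ground truth.

## Mesh model

A surface is a closed, consistently outward-oriented 2-manifold triangle
mesh in millimetres (`TriangleMesh`).  Validation rejects open
boundaries, non-manifold edges, inverted orientation and geometrically
degenerate faces (area < 1e-12 mm²) — slivers are rejected rather than
dropped because cotangent weights blow up on them.  Enclosed volume is
computed by the divergence theorem, `V = (1/6) Σ det(a, b, c)` over
faces: exact for polyhedra and resolution-independent, which is why the
volume-based metrics and the pre-dilation stopping rule are evaluated
mesh-side rather than by voxel counting.  Vertex normals are
area-weighted averages of incident face normals — a robust choice on
irregular stair-step geometry.  One-ring neighbourhoods are stored in
cyclic fan order so the two angles opposite each edge are paired
deterministically.

## Smoothing

All five methods share the simultaneous (Jacobi) update
`p_i(t+1) = p_i(t) + λ U(p_i(t))`: displacements are computed from
iterate *t* for every vertex and applied together.  In-place
(Gauss–Seidel) updates would make results depend on vertex order.

**Diffusion coefficient λ.**  Defaults are per-method and chosen by
stability analysis, since the operators have different gains:

* M1/M2/M5 (uniform and inverse-distance umbrella): the update is a
  convex combination of ring positions for λ ≤ 1; default **λ = 0.5**.
* M3 (scale-dependent umbrella): the operator has units mm⁻¹ and row
  sums ≈ 2/ē² for mean edge length ē, so the explicit step is only
  contractive for λ below roughly ē²/2 — about 0.125 at ē = 0.5 mm.
  Default **λ = 0.1**; `scale_dependent_stable_lambda(mesh)` reports the
  Gershgorin bound for any given mesh.
* M4 explicit (normalised cotangent flow): the clamped cotangent weights
  are normalised to unit ring sum but individual weights may be negative
  and large (|cot 1°| ≈ 57 against ring sums ≈ 8), so the update is not a
  convex combination; at λ = 0.5 the flow diverges on stair-step meshes
  within 30 iterations, at λ = 0.1 it is stable in all our experiments.
  Default **λ = 0.1**.  The implicit backward-Euler variant
  `(I − λ·dt·K) Pⁿ⁺¹ = Pⁿ` (default dt = 0.1) is unconditionally stable
  and provided as `curvature_mode="implicit"`.

**Cotangent curvature normal.**  The discrete mean-curvature normal at a
vertex is `−κ̄n = (1/4A) Σ (cot α_j + cot β_j)(p_j − p_i)` with A the
*local averaging region* of the vertex.  We take A as the mixed Voronoi
cell (Voronoi area inside non-obtuse incident triangles, area/2 or
area/4 fallback otherwise), which reproduces the analytic curvature
1/r of a sphere to 4 digits on a subdivided icosphere; normalising by
the full one-ring area instead underestimates the curvature threefold.
Opposite angles are clamped to [1°, 179°] before the cotangent because
stair-step meshes develop near-degenerate angles under smoothing;
negative weight sums are kept (only the magnitudes are bounded).

**Pre-dilation (M2).**  The "grow first, then smooth back" strategy:
every vertex is offset by a single global α along its unit vertex
normal, with α solved by bisection (to 1e-6 relative) so the enclosed
volume grows by `dilation_fraction` (default 5 %).  Interpreting the
dilation as +5 % *volume* rather than a literal millimetre offset keeps
the setting size-independent; the solved α is reported in every result
and manifest so the literal-offset reading can be reproduced.  Uniform
Laplacian iterations then run until one of:

1. `threshold` — |V − V₀| ≤ `volume_threshold`·V₀ (default 0.5 %);
2. `contact` — any vertex has strictly negative signed distance to the
   original surface (pseudonormal sign test, checked every iteration);
3. `cap` — 10 000 iterations, reported as non-convergence.

On severely undersampled inputs the contact rule dominates: the dilation
offset α is small (≈ 0.08 mm on the default phantoms) while a single
λ = 0.5 umbrella step moves stair-step corner vertices several times
that far, so M2 terminates after very few iterations and barely smooths.
That is a genuine property of the algorithm at this undersampling
severity, not an implementation artefact; on smooth or finely-sliced
inputs the threshold branch is reached instead (demonstrated in the test
suite on an icosphere, where M2 stops with |RVD| ≤ 0.5 %).  Note also
that with λ = 0.5 the per-iteration volume change can exceed the ±0.5 %
band width, so the threshold condition can be stepped over entirely.

## Metrics

RVD is the signed percentage volume change; its sign distinguishes
expansion (+) from shrinkage (−).  The Hausdorff distance is
vertex-sampled: exact point-to-triangle distances (KD-tree candidate
pruning with a provably complete search radius), with the directed
maxima taken over source-mesh vertices.  On stair-step geometry the
maximum occurs at vertices (step corners), where this sampling is exact.
Summary statistics (mean, population SD, RMS, max) pool the two directed
per-vertex fields; both SD and RMS are always reported.  Heat-map export
writes the mesh with a per-vertex `quality` scalar as ASCII PLY plus a
vertex-index→distance CSV; values round-trip bit-exactly.

## Phantoms

`generate_phantom` voxelises an analytic shape by the voxel-centre
inclusion rule on an anisotropic grid (default 0.5 × 0.5 × 2.0 mm,
mimicking thick-slice MRI) with ≥ 2 voxels of padding.  Shape families:

* `ellipsoid` (default semi-axes 6 × 5 × 4 mm, analytic volume 502.7 mm³);
* `superellipsoid` (exponent p ≥ 2, closed-form volume via Γ functions);
* `ridged-blob` (default): radius function
  `R(u) = R₀ (1 + Σ_k a_k exp(−θ_k²/2w²))` with seeded lobe directions
  and amplitudes (R₀ = 5.5 mm, 6 lobes, |a| ≤ 0.12, w = 0.45 rad),
  mimicking articular facets and ridges; the analytic volume is computed
  by high-resolution spherical quadrature of R³/3.

Defaults put the phantoms in the small-bone regime (≈ 500–900 mm³).
Surface extraction: `voxel-faces` emits the boundary quads of the
occupied region split into triangles and welded on the voxel lattice —
its signed volume equals voxel count × voxel volume *exactly*, which the
tests assert to 1e-9 — or `marching-cubes` (0.5 iso-surface) for a less
terraced baseline.

**What the phantoms do not emulate:** image noise, segmentation error,
partial-volume effects, cortical/trabecular intensity structure, or
multi-bone scenes with contacting surfaces.  With ~5 slabs across the
object they sit at the severe end of undersampling; passing orderings on
them show how the methods rank under extreme stair-stepping, not what
their absolute errors would be on clinical-resolution data (which are
far smaller).  In particular, the heavy per-iteration volume loss at
this severity changes the character of M2 (see above) relative to what
finer data exhibit.

## Numerical choices

* Weld tolerance at load: 1e-9 mm (exact-duplicate welding, as produced
  by STL's per-facet vertex storage); looser welds would corrupt
  stair-step geometry.
* Inward-oriented input meshes are flipped to positive volume with the
  flip recorded in provenance; all other invariant violations are
  rejected, not repaired.
* Dilation bisection brackets α in [0, 2 × bounding-box diagonal] and
  fails loudly if the bracket does not contain the target volume.
* Signed distances use angle-weighted pseudonormals with the closest
  feature (face/edge/vertex) classified from barycentric coordinates —
  the standard robust sign test for closed meshes.
* Everything is deterministic: the only randomness in the package is the
  seeded lobe placement of the ridged-blob phantom.

## Known limitations

* The explicit curvature flow remains prone to local oscillation on
  meshes with near-degenerate triangles even at λ = 0.1; the implicit
  mode is the robust alternative.
* The contact rule tests mesh vertices, not interior points of faces; a
  face could in principle dip inside between vertices undetected.
* Hausdorff maxima are vertex-sampled on the source mesh, exact only
  when the maximum occurs at a vertex (typical for stair-step surfaces).
* Masks are assumed binary or integer-labelled; no fuzzy or probabilistic
  segmentations.
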