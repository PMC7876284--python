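# Methods

This note documents the models, numerical choices and limitations behind
`spinefsu`, in the order the pipeline runs them.

## Synthetic anatomy

**Vertebra model.** A vertebra is a star-shaped closed surface built on a
fixed icosphere template (default 2 subdivisions of a refined icosahedron,
642 vertices): the radius along each template direction is a superellipsoid
body term (exponent 6, so the endplates are near-flat and the walls steep,
like a real vertebral body) plus smooth angular Gaussian bumps for the
posterior elements — left/right transverse processes, spinous process,
posterior arch, and paired superior/inferior articular processes. All
meshes generated at one template resolution share vertex count and
connectivity exactly, which gives point-to-point correspondence for free.
With `asymmetry = 0` and `noise = 0` the template is mirror-symmetric about
the sagittal plane to machine precision (the icosphere vertex set maps onto
itself under x → −x, and midline ligament sites are restricted to
sagittal-plane vertices).

Default body dimensions (42 × 34 × 28 mm) with default process lengths give
overall extents near 85 mm left-right and 80 mm anterior-posterior — the
scale of an average healthy lumbar vertebra. Fidelity beyond the features
the pipeline consumes (four separable regions, two endplates, articulating
facet patches, seven ligament sites) is deliberately not a goal.

**Facet articulation.** The superior articular processes sit lateral with
medial-facing cartilage patches; the inferior processes of the vertebra
above sit medial with lateral-facing patches, so adjacent vertebrae
interlock on near-vertical surfaces as lumbar facets do. Facet patches are
the articulating flank of each process (bump region filtered by vertex
normal direction). The default facet joint space is 1.0 mm, a physiological
cartilage gap.

**Ground truth.** Per-vertex semantic labels (body / left / right /
spinous+lamina) are assigned from the template direction; landmarks are
area-weighted region centroids projected on the surface; endplate patches
cover the flat caps minus process exclusions; ligament sites (ALL, PLL,
SSL, ISL, LF, left/right ITL) are named template vertices.

**Populations.** `generate_population` displaces the base mesh along K
smooth orthonormal fields (low-order polynomials of the template direction,
projected off the six rigid-body generators and QR-orthonormalized) with
zero-mean normal coefficients. Scales are expressed in the 3N-embedding
norm; the defaults (60, 40, 25 mm) correspond to per-vertex RMS
displacements of roughly 2.4/1.6/1.0 mm — realistic inter-subject shape
variation. Because the fields are orthogonal to rigid motions, Procrustes +
PCA recovers the spanned subspace essentially exactly, which is what the
shape-model recovery tests assert.

**FSU assembly.** The upper vertebra is translated along +z until the mean
closest-point distance between the opposing labelled endplates equals the
requested disc height (scalar root find); facet clearance below the
requested joint space is restored by iteratively displacing only the upper
inferior facet patch along the patch separation direction — the automatic
facet-joint gap creation the pipeline also applies to fitted clinical
meshes.

**Rasterization.** Label volumes use the voxel-center-inside convention,
computed by a winding-parity column sweep (exact for watertight meshes).
Default spacing is 0.39 × 0.39 × 0.5 mm, the CT resampling resolution the
pipeline targets; the desk-scale pipeline default is 0.8 mm isotropic.
Boundary noise perturbs each label's signed distance field with a smoothed
Gaussian random field of the stated voxel-unit amplitude, emulating
imperfect automated segmentation.

## Mesh metrics

DC is voxel overlap 2|A∩B|/(|A|+|B|); when one of the inputs is a mesh it
is voxelized on the ground-truth grid first. MSD/HD are vertex-sampled with
exact point-to-triangle distances and symmetrized (MSD averages the two
directed means, HD takes the max of the two directed maxima). HD is the
exact maximum, not a percentile. Closest-point queries are exact for meshes
up to 4096 faces and KDTree-prefiltered (48 candidate triangles) above —
indistinguishable in practice and verified against the exact path.

`resample_to_count` produces exactly N vertices by casting rays from the
volume centroid along a Fibonacci-sphere direction set triangulated by its
convex hull. This is exact for star-shaped surfaces (all synthetic anatomy
here); rays that miss fall back to the nearest surface point. The default
N = 2947 matches the fixed point count of the part classifier's full-scale
configuration.

## Semantic part classifier

Architecture: linear encoder 3 → F, a stack of feature-steered graph
convolutions with ReLU, linear F → 4 logits, per-vertex softmax. Scaled-down
defaults: N = 1000 vertices, 3 convolution layers, F = 16 features, M = 8
attention matrices, 60 epochs — desk-scale; depth and width are config.
Inputs are vertex coordinates centered and scaled to unit bounding-box
diagonal (needed for training stability). Training is full-mesh Adam steps
(learning rate 10⁻³, ε = 10⁻⁸) on per-vertex softmax cross-entropy, the
standard loss for an N × 4 logits soft assignment. Forward and backward
passes are hand-written numpy (verified against finite differences and a
naive dense implementation); fixed data + seed reproduce the weights
bit-exactly. Argmax ties break toward the lowest class index.

The geometric fallback (`heuristic_parts`) classifies by direction from the
vertex centroid — anterior = body, posterior split into left/right/medial —
and mirrors exactly under reflection. On default synthetic vertebrae it
agrees with the generator truth at ≳0.9.

## Shape models and fitting

Per-level models are built by generalized Procrustes alignment (rotation +
translation only; scale is a shape difference the modes should carry,
convergence when the mean moves < 10⁻⁶ mm RMS) followed by PCA of the
aligned vertex coordinates. Coefficients are expressed in per-mode standard
deviations throughout; the default synthetic harness builds one model per
level from populations of 50 shapes.

Fitting runs in two phases after landmark rigid initialization and ICP:

1. a coarse alternating phase (closest-vertex correspondences; pose by
   Kabsch; coefficients by regularized linear least squares with the four
   landmark correspondences as additional weighted rows, default landmark
   weight 1.0, regularization 0.1, coefficients clipped to |b| ≤ 3 sd);
2. a fine joint Gauss-Newton phase on the point-to-plane metric over pose
   and coefficients together. The landmark rows are dropped here: derived
   landmarks are centroids-of-regions and carry a small definition bias, so
   the fine registration is purely surface-driven. Point-to-plane resolves
   the tangential-sliding slowness of point-to-point updates and converges
   in a handful of iterations.

The final step projects each fitted vertex to its nearest ray-surface
intersection along ± its normal (bounded ray length; vertices without a hit
stay put; vertices whose projection would invert faces are reverted). The
fitted and projected meshes always keep the template topology — the
correspondence contract the FE builder relies on.

## FE model assembly

* **Bone.** No tetrahedral mesher is assumed: the interior is sampled on a
  voxel lattice (pitch = largest extent / 24 by default) and each voxel is
  split into six conforming tetrahedra (Kuhn decomposition), which
  guarantees positive Jacobians. Elements with centroids within the shell
  thickness (default 1.0 mm) of the surface are cortical, the rest
  trabecular; the geometric split rule is a package choice — published
  parameter tables distinguish the two materials without stating the rule.
  One-element-deep endplate element sets are tagged from the surface
  patches. Bone volumetric meshes matter for the FEBio export; the internal
  solver treats vertebrae as rigid.
* **Disc.** An elliptical footprint is fitted to the intersection of the
  two endplate patches (90% of the intersection box) and a structured
  n×n×n_axial hex grid (default 6×6×3) is stretched between the endplate
  surfaces by vertical ray projection, so every bottom/top boundary node
  lies on its endplate surface within 10⁻⁶ mm and the disc height equals
  the mean endplate distance by construction; those nodes are kinematically
  tied to the owning vertebra (the tied-contact idealization). The central
  elements closest to 44% of the disc volume are the nucleus (cut only
  between whole radius rings, preserving bilateral symmetry); annulus
  elements carry two unit fiber directions at ±30° to the transverse plane,
  criss-crossing circumferentially. Nucleus fraction and fiber angle are
  standard lumbar values and configurable.
* **Ligaments.** One tension-only nonlinear element per named site pair;
  rest length = attachment distance; piecewise-linear force-strain curves
  (compliant toe, stiffer linear branch) with library defaults scaled to
  published lumbar force-deflection magnitudes, all configurable.
* **Materials.** Healthy: orthotropic cortical bone (E₁ = E₂ = 8000,
  E₃ = 12000 MPa; shear moduli are package defaults of 3500 MPa — absent
  from the standard table), neo-Hookean trabecular bone (E = 100, ν = 0.2),
  endplates (E = 1000, ν = 0.3), nucleus (E = 1, ν = 0.49) and facet
  cartilage (E = 30, ν = 0.4); Holmes-Mow annulus (E = 1, ν = 0.4,
  β = 3.4) with two exponential-power fiber families (ξ = 0.296, α = 65,
  β = 2). Pfirrmann corrections: grade 4 → nucleus E 1.4 MPa / ν 0.42,
  annulus E 4.5 MPa; grade 5 → nucleus E 2.2 MPa / ν 0.32, annulus
  E 5.5 MPa; everything else unchanged. Grades 1–3 have no defined
  correction and are rejected.
* **Export.** FEBio 2.5 XML: 1-based contiguous node/element ids, tet4 bone
  blocks per material, hex8 nucleus/annulus, tri3 facet-cartilage shells and
  the rigid loading plate, tied disc-endplate and sliding facet contacts,
  nonlinear-spring ligaments with their curves, the fixed inferior-endplate
  node set, and the pure moment as a rigid-body load ramped by a linear load
  curve. Geometry is in mm and moments in N mm (7.5 N m → 7500). The
  package's own reader parses these files back losslessly.

## Quasi-static ROM solver

The solver minimizes total potential energy over the upper vertebra's rigid
pose (rotation vector + translation) and the free interior disc nodes;
bottom disc nodes are fixed with the lower vertebra, top nodes move rigidly
with the upper. Bone elasticity is deliberately omitted internally (bone is
2–4 orders stiffer than the disc) while remaining in the FEBio export.

Energy terms, all with analytic gradients that the test suite verifies
against central finite differences at 10⁻⁵ relative tolerance:

* hex elements with 2×2×2 Gauss quadrature; compressible neo-Hookean
  W = μ/2 (I₁−3) − μ ln J + λ/2 (ln J)² for the nucleus; compressible
  Holmes-Mow W = c/2 (e^Q − 1), Q = β/(λ+2μ) [(2μ−λ)(I₁−3) + λ(I₂−3)] −
  2β ln J, c = (λ+2μ)/(2β) for the annulus, which reduces to the quadratic
  polynomial core as β → 0; fibers W = ξ/(αβ̄)(exp(α(Iₙ−1)^β̄) − 1) active
  only for Iₙ > 1, evaluated at the same Gauss points for both families;
* ligaments: stored energy is the integral of the piecewise-linear tension
  curve over elongation, zero in compression;
* facet contact: each joint contributes two linearized half-space gap
  constraints — the articular-plane normal (±45° to the sagittal plane,
  configurable) and a vertical tip-abutment normal — with per-vertex rest
  clearances taken from the exact geometry, penalty stiffness 200 N/mm per
  unit reference area, frictionless. The linearization keeps the energy
  smooth (a requirement for the quasi-Newton solver) and reproduces the
  physiological roles of the joint: the contralateral facet stops axial
  rotation, both engage in extension and ipsilateral bending, flexion
  disengages;
* external load: a pure moment enters as −m·r, the rotation-vector work
  conjugate — exact to second order in the rotation and adequate at
  physiological angles; optional forces enter as −f·t.

Numerical safeguards: ln J is continued quadratically (C²) below J = 0.2
and the exponentials above 30, so extreme line-search trial states stay
finite and strongly penalized instead of raising; rotation degrees of
freedom are scaled by a geometric lever (mean node distance from the disc
centroid) so pose and nodal gradients share one magnitude. Each load
increment is solved with L-BFGS-B (warm-started, deterministic), with a
second tightening pass if the residual is marginal; convergence is an
honest flag: max |∇E| ≤ tol × load scale (default tol 10⁻⁶). Default
protocol: 6 increments per branch to ±7.5 N m.

The intersegmental rotation is the component of the upper body's rotation
vector along the load axis, in degrees; ROM is its magnitude at peak
moment. The mesh-convergence study rebuilds the model with surfaces and
disc grid down-sampled by factors 1, 1.2, 1.5, 2, 3 and reports ROM and
successive differences; the coarsest factors may legitimately fail to
assemble or converge, which is reported rather than raised.

## Problem sizes

Defaults used by the test suite and the acceptance script: 642-vertex
vertebra templates, 1000-vertex classifier meshes, populations of 40–50
shapes, 6×6×3-element discs (108 hexes, ~160 free degrees of freedom),
label volumes at 0.8–1.2 mm spacing, 3–6 load increments. These sizes keep
a full run in minutes on one CPU while leaving every algorithmic path
exercised; all of them scale up through configuration.

## What the synthetic data does and does not show

The generator reproduces the *structural* features the pipeline needs —
correspondence, separable regions, articulating facets, endplate-bounded
discs, known low-rank shape variation, controllable segmentation noise —
so passing tests demonstrate the correctness of the algorithms and the
internal consistency of the chain. It does not reproduce real vertebral
cortical geometry, osteophytes, fractures, CT intensities or true
population statistics, so test metrics (Dice, MSD, HD, ROM values) are not
predictions of clinical performance; only their directions of change (e.g.
registration filtering out large Hausdorff outliers, ROM decreasing with
disc degeneration, left/right asymmetry under asymmetric facet narrowing)
are expected to transfer.

## Known limitations

* The internal solver's rigid-vertebra and linearized facet-gap
  idealizations trade fidelity for robustness; the exported FEBio model
  carries the full bone elasticity and true contact surfaces.
* `resample_to_count` assumes a star-shaped input; strongly non-convex
  clinical surfaces would need a different remesher behind the same
  interface.
* Ligament curves and cortical shear moduli are literature-shaped defaults,
  not validated parameters.
* Patient-specific material mapping from image intensities is out of scope
  by design; only geometry is patient-specific.
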