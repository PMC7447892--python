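# Methods

`flocfrac` reconstructs micron-scale protein precipitate particles ("flocs")
in 3D from wide-field light-microscopy z-stacks and characterizes each
particle by its box-count fractal dimension and morphometrics. This note
records the models, conventions and numerical choices, and what the synthetic
test bed does and does not establish about real data.

## Imaging model and focal-plane segmentation

A wide-field stack images the same field at focus heights spaced `dz` apart.
Every particle appears in every slice, but only the optical section near the
focus height has sharp outlines; content away from focus is blurred. The
segmentation exploits exactly this: a slice is binarized from its *in-focus
edges* rather than from an intensity threshold (which cannot distinguish
in-focus from out-of-focus brightness).

Per slice:

1. **Edge detection.** Prewitt gradient magnitude, thinned to local maxima
   along the quantised gradient direction, thresholded at
   `edge_threshold × level`. The level is Otsu's threshold over the nonzero
   gradient magnitudes *pooled over the whole stack*, so all slices are
   judged against the stack's sharp edges; a slice with only defocused
   content then yields (nearly) nothing. Edge magnitude is polarity-agnostic,
   so dark-on-bright and bright-on-dark objects segment identically.
   `edge_threshold` defaults to 1.0 (the automatic level unchanged).
2. **Closing.** Morphological closing with a disk, default radius 2 px,
   bridges the 1–4 px gaps typical of detected outlines at ~0.1 µm/px.
3. **Filling.** Interior holes fully enclosed by edge pixels are filled
   (2D, per slice — the stack is sectioned before it is assembled). Open
   arcs are left unfilled.
4. **2D border clearing.** Components touching the image border are removed
   (truncated objects). Border clearing is applied again in 3D after
   labeling; the two operate at different stages and both are kept.

Known, accepted bias: for a sharp step edge the gradient ridge straddles the
boundary, so filled masks carry roughly a +1 px shell. For a radius-14 voxel
object this inflates the recovered volume by ~15–20 %; the end-to-end
recovery tests budget for it.

## Reconstruction and exclusion filters

Slice masks are stacked in acquisition order into a boolean `(z, y, x)`
volume that is to scale via its `VoxelGeometry` (defaults `dx = dy =
0.092 µm`, `dz = 0.198 µm`). Connected components are labeled with
26-connectivity by default ("standard connectivity" of common 3D object
detection; 6 and 18 are available). Three filters run in a fixed order —
small objects → border-touching → pillars — and order invariance is
deliberately not claimed:

* **Small objects** (default < 50 voxels) are dust/interference artifacts.
  This is distinct from the population-level 5000-voxel cut (below).
* **Border-touching** components (any voxel on any of the six faces,
  including the first/last slice) are likely truncated.
* **Pillars.** An interference spot appears identically in every slice
  regardless of focus, so it reconstructs as a column spanning the stack.
  Formal rule: a component is a pillar iff its z-extent covers ≥ 95 % of the
  slices *and* the mean Jaccard similarity between its per-slice footprint
  and its overall xy-projection is ≥ 0.9. Real particles change their
  optical section slice to slice and fail the second condition even when
  tall. Note that a pillar spanning the *entire* stack touches both z faces
  and is already removed by the border filter; the footprint rule catches
  pillars that fall just short of the faces.

## Morphometrics

All on the original anisotropic grid, in physical units:

* **Volume** = voxel count × `dx·dy·dz`.
* **Diameter** = diameter of the exact minimal sphere enclosing all voxel
  centres (Welzl's move-to-front algorithm over convex-hull vertices; not an
  approximation; verified against O(n⁴) support-set enumeration). The sphere
  encloses voxel *centres*; enclosing voxel cubes instead would add at most
  one pixel diagonal to the diameter.
* **Density** = volume / volume of the enclosing sphere, in (0, 1]; the
  image-analysis proxy for packing density (true mass density is not
  recoverable from images). A single voxel has density 1 by convention.
* **Surface area** = exposed voxel faces weighted by their physical face
  areas (Manhattan surface). Exact and oracle-testable; its bias relative to
  a smooth surface is consistent across particles, which is what population
  comparisons need. Surface-to-volume ratio proxies surface-to-mass under
  the constant-protein-density assumption.

## Box-count fractal dimension

`N(ε)` counts boxes of side ε (single grid anchored at the array origin;
partial boxes at the far edges count) containing any foreground. For a
fractal, `N ∝ ε^(−D)`; `D` is minus the OLS slope of `ln N` vs `ln ε`,
reported positive: 3 for a filled cube, 2 for a filled square, 1 for a
straight rod (all exact on power ladders, to 1e-6 in the test battery), and
log 20 / log 3 ≈ 2.7268 for the Menger sponge on its triadic ladder.

Conventions:

* **Ladder**: powers of two from 1 up to the largest ≤ the smallest side of
  the particle's tight bounding box, extended toward the largest side when
  fewer than three sizes result (a fit needs ≥ 3 points).
* **3D counting always runs on the isotropically resampled particle** (each
  slice replicated `round(dz/dx)`× in z, geometry updated accordingly):
  boxes must be cubic in physical space. Morphometrics stay on the original
  grid; the population voxel-count threshold refers to the original grid.
* **Fit**: OLS over all ladder points by default; `fit_range` restricts the
  window. Local slopes between adjacent ladder points feed the
  **monofractality flag**: r² ≥ 0.98 *and* no local slope deviating from the
  global D by more than 0.15 (both configurable; they are package choices —
  "a linear log-log curve" has no canonical cutoff).
* **Grid anchor**: single anchor (no offset averaging) to match the common
  dyadic box-count routine; offset averaging is easy to add but changed
  measured dimensions of test aggregates by < 0.03 in our checks.

### Fit windows are regime-specific

A finite object scales fractally only between its smallest resolved feature
and its overall extent, and the informative window differs by object class:

* **Solids (sphere calibration).** A pixelated solid has no internal
  structure; boxes comparable to the object measure its convex envelope
  (N saturates toward 1) and drag the slope down non-monotonically.
  `sphere_calibration` therefore fits the fine-scale window
  (ε ≤ min side / 8, at least the three smallest ladder points), where the
  pixelation bias it is designed to quantify actually lives. With that
  window the calibration is monotone in size and approaches 3 from below
  (≈ 2.85 at radius 30, ≈ 1.97 at radius 3) — the size-dependent resolution
  bias that must be kept in mind when small and large particles are
  compared. `bias_correct` adds `3 − D_sphere(voxel count)` (log-linear
  interpolation, nearest endpoint outside the calibrated range with a
  warning) and is always reported alongside, never instead of, the raw D.
* **Monomer-built aggregates.** Below a few monomer diameters box counting
  sees the solid strands (local slopes fall toward the strand skeleton's),
  above ~half the cluster extent it sees the envelope. `aggregate_dimension`
  fits ε ∈ [4 × monomer diameter, min bounding side / 2] on the
  power-of-two ladder spanning the bounding box.
* **Per-particle pipeline metrics** keep the full-ladder default: real
  precipitate particles are resolved well above the pixel scale and their
  whole-curve linearity is itself the monofractality diagnostic.

## Population statistics

Condition-level summaries use particles strictly larger than 5000 voxels
(original grid) to suppress the resolution bias quantified by the
calibration. Mean and *sample* SD (n−1) of D, density and surface-to-volume
are reported; the SD is the particle-to-particle spread of the population —
deliberately large compared with SDs of ensemble-averaging instruments — and
no standard errors or significance tests are attached. `rank_conditions`
orders conditions along a user-given expected-shear ranking and reports a
descriptive flag for a non-decreasing mean D (shear-aged flocs compact as
loose branches shear off). `camp_number` computes the aging parameter
γ = √(P / (V ρ ν)) (power input W, reactor volume m³, suspension density
kg/m³, kinematic viscosity m²/s).

## Synthetic test bed

No real stacks ship with the package; every stage is exercised against
generated ground truth.

* **Solids**: spheres (voxel centre inside the analytic radius), cubes, rods,
  Menger sponges — closed-form voxel counts and known dimensions.
* **DLA.** Off-lattice particle-cluster diffusion-limited aggregation:
  walkers launched from a sphere just outside the cluster, walk-on-spheres
  jumps far from it, steps of one monomer radius near it, *exact*
  segment/contact-sphere first-crossing deposition (overshoot-and-project
  deposition measurably opens the cluster: mass-radius exponent 2.27 vs 2.36
  with exact hits at n = 5000), kill radius 10× the launch radius with
  uniform relaunch. Sticking probability 1 models the diffusion-limited
  regime appropriate for slowly diffusing macromolecules such as antibodies;
  lower values emulate reaction-limited growth. Bit-reproducible given
  (n, monomer radius, seed).
* **Finite-size bias of the aggregate dimension.** The asymptotic dimension
  of particle-cluster DLA is ≈ 2.5, bracketing the ~2.4 expected of
  diffusion-limited precipitation. At 10,000 monomers the usable scaling
  window is barely over a decade and `aggregate_dimension` reads ≈ 2.15;
  at 30,000 monomers ≈ 2.24, still climbing with size. This is a property
  of box counting finite clusters, not of the generator (whose mass-radius
  scaling and Rg(n) prefactor match the known values); comparisons against
  the diffusion-limited expectation therefore use the largest clusters the
  time budget allows (30,000 monomers in the test suite) and must expect a
  residual downward bias of ~0.15 at that size.
* **Virtual microscope.** Slice k is the maximum projection over truth
  slices m of their silhouettes blurred with
  σ(k,m) = √(σ₀² + (c · max(0, |z_k − z_m| − DOF/2))²), plus background,
  Gaussian noise, and optional interference-spot discs repeated identically
  in every slice (the pillar artifact), clipped to [0, 1]. Defaults are set
  from the optics of a 100×/1.40 NA oil objective at 0.092 µm/px: geometric
  defocus blur for that aperture grows by roughly ≈ 26 px per µm of defocus,
  so σ₀ = 0.6 px, c = 8 px/µm is conservative; DOF = λn/NA² ≈ 0.3 µm; noise
  SD 0.02, background 0.1 of full scale. With zero blur growth the model
  degenerates to ideal sectioning (out-of-focus planes rejected entirely).
  It is *not* a physical PSF: no diffraction rings, no spherical aberration,
  no photon statistics. Passing the recovery tests therefore shows the
  pipeline handles defocus-dominated stacks with realistic noise, not that
  it is robust to every real-world aberration.

### Problem sizes used by the test suite

End-to-end recovery runs a 44 × 220 × 220 scene (five target solids of
radius 14–16 voxels / side 26, one object flush with an xy face, one
touching the first z slice, two interference spots) — large enough that the
+1 px segmentation shell stays within the 30 % volume budget, small enough
to render in seconds. The aggregate-regime check uses 8 × 30,000-monomer
clusters; oracle-equivalence checks run 100 random trials each against
brute-force enumeration (box scan ≤ 64²/32³, flood fill ≤ 20³, minimal
sphere ≤ 50 points at 1e-9 µm).

## Known limitations

* Touching particles are not split (no watershed); they count as one.
* The Manhattan surface overestimates smooth-surface area by a
  shape-dependent factor (≤ 1.5 for a sphere); only comparisons within the
  same convention are meaningful.
* Box-count D of small particles is resolution-biased low; use the
  calibration correction or the 5000-voxel population cut.
* The z-extent of recovered particles is slightly over-detected (slices
  within ~1 DOF of a surface still show sharp edges).
* Geometry is trusted from user input; TIFF resolution tags are only warned
  about, never used.
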