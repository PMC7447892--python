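# flocfrac

3D reconstruction and fractal analysis of protein precipitate particles from
wide-field light-microscopy z-stacks.

Precipitating antibodies with PEG is a cheap capture step, but the 3D
structure of the precipitate flocs — how dense, how branched, how it varies
from particle to particle — drives recovery, dissolution and scale-up, and
is invisible to turbidity or average-scattering measurements. `flocfrac`
implements a light-microscopy route to that structure: a z-stack of one
field is binarized slice by slice from its *in-focus edges* (out-of-focus
content has shallow gradients and drops out), the binary slices are stacked
into a to-scale 3D volume, connected components become individual particles,
and each particle is characterized by its box-count fractal dimension and
morphometrics. Because every particle is resolved individually, the output
is a *distribution* of fractal dimensions per process condition, not a
single ensemble average.

The core statistic is the box-count dimension: cover the particle with boxes
of side ε and count the occupied boxes N(ε); for a fractal

    N(ε) ∝ ε^(−D),

so D is minus the slope of ln N vs ln ε — 3 for a filled cube, 2 for a
filled square, lower for porous or branched structures. A linear log-log
curve over the whole ladder (monofractality) means one D describes the
particle at every observed scale. Supporting quantities per particle:
volume (voxel count × voxel volume), diameter of the exact minimal
enclosing sphere (Welzl's algorithm), density (volume over enclosing-sphere
volume), and Manhattan surface area / surface-to-volume ratio. Population
tools aggregate particles above a 5000-voxel cut into per-condition
mean ± SD, histograms, a shear-ranking trend check, and the Camp number
γ = √(P/(Vρν)) utility for relating conditions to shear.

Because real stacks are rarely shareable, the package ships a synthetic test
bed: deterministic solids (spheres, cubes, rods, Menger sponges), an
off-lattice particle-cluster diffusion-limited aggregation (DLA) simulator
(the growth model matching diffusion-limited precipitation of slowly
diffusing macromolecules), and a virtual wide-field microscope (defocus
blur, noise, interference-spot "pillar" artifacts) so the entire pipeline is
exercisable end to end against known ground truth. See `docs/methods.md`
for models, conventions and limitations.

## Worked example

```python
from flocfrac import (MicroscopeModel, RunConfig, VoxelGeometry, camp_number,
                      place_solids, render_stack, run_stack, solid_sphere)

geometry = VoxelGeometry(dx=0.092, dy=0.092, dz=0.198)   # µm per voxel edge
truth = place_solids((40, 160, 160),
                     [(solid_sphere(14), (6, 20, 20)),
                      (solid_sphere(11), (10, 90, 90))],
                     geometry=geometry)
stack = render_stack(truth, MicroscopeModel(interference_spots=1,
                                            spot_positions=((40, 120),)),
                     seed=7)
metrics = run_stack(stack, RunConfig(), condition="batch_low")
for m in metrics:
    print(f"particle {m.label}: {m.voxel_count} voxels, "
          f"volume {m.volume_um3:.2f} µm³, diameter {m.diameter_um:.2f} µm, "
          f"density {m.density:.2f}, D = {m.fractal_dimension:.2f} "
          f"(r² = {m.fit_r2:.3f}, monofractal = {m.monofractal_flag})")
print(f"Camp number of a 2 W, 1 L water-like reactor: "
      f"{camp_number(2, 1e-3, 1000, 1e-6):.0f} s⁻¹")
```

prints

```
particle 1: 13107 voxels, volume 21.97 µm³, diameter 5.64 µm, density 0.23, D = 2.65 (r² = 0.999, monofractal = False)
particle 2: 6707 voxels, volume 11.24 µm³, diameter 4.47 µm, density 0.24, D = 2.54 (r² = 0.998, monofractal = False)
Camp number of a 2 W, 1 L water-like reactor: 1414 s⁻¹
```

Both rendered spheres are recovered (the interference pillar is filtered
out), with volumes within ~15 % of ground truth. At this anisotropy a
voxel-sphere is physically an ellipsoid elongated 2.15× in z, so its
enclosing-sphere density is well below a ball's; the D values show the
finite-resolution bias of compact objects quantified by
`flocfrac.sphere_calibration`, and the strict monofractality flag reflects
the envelope curvature of a solid body's box-count curve — genuinely
scale-free objects (e.g. a Menger sponge) flag true.

The same stages are available as a CLI:
`flocfrac simulate | segment | reconstruct | analyze | report`, e.g.

```bash
flocfrac simulate --kind dla --n 10000 --seed 7 --out truth.tif
flocfrac segment --input stack.tif --dx 0.092 --dy 0.092 --dz 0.198 --out masks.tif
flocfrac reconstruct --masks masks.tif --min-voxels 50 --out labels.tif
flocfrac analyze --labels labels.tif --condition batch_low --out metrics.csv
flocfrac report --metrics metrics.csv --min-voxels 5000 --out summary.csv
```

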