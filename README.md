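# memdeform

Membrane-deformation analysis for molecular-dynamics trajectories of
membrane proteins — built around the question of how an ER insertase (the
Get1/Get2 heterotetramer bound to the Get3 ATPase dimer) locally thins and
distorts the lipid bilayer it sits in.

The package post-processes atomistic MD trajectories (or its own synthetic
stand-ins) into three products:

1. **2D leaflet thickness maps.** Per frame, lipid phosphorus atoms are
   split into upper/lower leaflets about their median z; each leaflet's
   z-coordinates are interpolated onto an xy grid with a C1 piecewise-cubic
   Clough–Tocher interpolant on the Delaunay triangulation of the (x, y)
   positions; the two surfaces are subtracted; and the per-cell difference
   `T(x, y) = z_upper(x, y) − z_lower(x, y)` is averaged over time and
   simulation repeats. A 2D lateral density of the transmembrane helices can
   be overlaid to locate the protein, and a radial Gaussian well
   `T(r) = T0 − D·exp(−r² / 2σ²)` can be fitted to quantify protein-induced
   thinning (depth `D`, lateral width `σ`).
2. **3D iso-occupancy volumes.** Per voxel, the fraction of frames in which
   at least one selected atom (lipid phosphorus) visits it; iso-surfaces
   (default level 0.6) are extracted by marching cubes and exported as
   OpenDX / Wavefront OBJ for VMD, PyMOL or ChimeraX.
3. **Structural geometry.** The membrane normal defined as the ATPase
   dimer's C2 symmetry axis (from the Kabsch rotation between its two
   chains), helix axes by principal-component fits of Cα traces, tilt and
   inter-helix angles, helix lengths, lipid-tail tilt, and buried interface
   areas from Shrake–Rupley solvent-accessible surface areas.

Before mapping, every frame is superposed to a reference **on the membrane
plane only** (rotation about z plus translation), so the bilayer is never
tilted out of its plane by the alignment; equilibration frames (default
first 200 ns) are discarded.

A seeded synthetic bilayer generator (two leaflets of diffusing phosphorus
particles riding on analytic surfaces with a Gaussian thinning well and
ideal-helix protein bundles) provides exact ground truth for every stage.

## Worked example

```python
import memdeform as md

spec = md.SyntheticBilayerSpec(T0=40.0, D=8.0, sigma_w=15.0, noise_z=2.0,
                               n_per_leaflet=256, n_frames=100,
                               n_replicates=3, seed=42)
trajs = md.generate_replicates(spec)
p = md.select_phosphorus(trajs[0].topology)
grid = md.GridSpec2D.from_box(trajs[0].boxes[0])
tmap = md.thickness_map(trajs, p, grid)
print(f"spatial mean thickness: {tmap.spatial_mean():.2f} A "
      f"over {int(tmap.defined_mask.sum())} cells")
result = md.ThinningWellModel(tmap, tuple(spec.well_center)).fit()
print(result.summary())
```

Output:

```
spatial mean thickness: 39.21 A over 3600 cells
Radial Gaussian thinning-well fit
  cells used: 3600   center: (60.00, 60.00)
  residual RMS: 0.2523 A
  parameter                         estimate     std err
  T0 (far-field thickness, A)        39.9949      0.0054
  D (well depth, A)                   7.8945      0.0268
  sigma (well width, A)              15.0539      0.0415
```

The map's spatial mean (39.21 Å) is below the nominal 40 Å because of the
thinning well; the fit separates the far-field thickness (`T0` ≈ 40 Å)
from the well depth (`D` ≈ 8 Å) and width (`σ` ≈ 15 Å), recovering the
generator's parameters to about 1%.

The same pipeline runs from the shell:

```sh
memdeform simulate  --config examples/bilayer.yaml --out run/sim
memdeform thickness --config examples/analysis.yaml --out run/thickness
memdeform occupancy --config examples/analysis.yaml --out run/occupancy
memdeform geometry  --structure model.pdb --selections examples/selections.yaml --out run/geometry
```

For real data, point `topology` at a PDB/mmCIF file and `trajectories` at
XTC/TRR/DCD files; selections (transmembrane residue ranges, helix
boundaries) are given in the YAML config.

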