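# Methods

This note records the models, conventions and numerical choices behind
memdeform, in the spirit of the methods documentation of mature simulation
and analysis packages.

## Problem setting

A membrane protein such as the GET insertase (the Get1/Get2 heterotetramer
with its Get3 ATPase dimer) perturbs the bilayer around it: the membrane is
locally thinner near the protein, and the cytosolic leaflet is distorted
more strongly than the luminal one, particularly at the mouth of the
hydrophilic groove through which tail-anchored substrates insert. memdeform
quantifies these effects from MD trajectories through three products: 2D
leaflet thickness maps, 3D iso-occupancy volumes of lipid headgroups, and
the helix-tilt geometry of the protein itself.

## Frame preparation

**Equilibration.** Frames with time ≤ `t_cut` are discarded (strict
inequality: the boundary frame belongs to the discarded equilibration
period). The default `t_cut` of 200 ns matches typical membrane-relaxation
times for a protein of this size; the windowed thickness time series
(`thickness_timeseries`) is the diagnostic for choosing it — the spatial
mean thickness should have plateaued before `t_cut`.

**In-plane superposition.** All frames are superposed to a reference on the
membrane (xy) plane: the rigid motion is restricted to a rotation about z
plus a free translation. The in-plane part is the 2D least-squares
(Kabsch-type) fit over the transmembrane Cα selection,
`θ = atan2(Σ(m×r), Σ(m·r))` on centered coordinates; z is shifted by the
selection's centroid offset only. An unrestricted 3D superposition would
rotate the bilayer out of its plane and contaminate the thickness maps with
alignment artifacts; it is available behind `full_3d=True` for comparison.
Whether the per-frame z-offset should be removed at all is a genuine
choice; removing it references each frame's map to the protein's vertical
position, which is what a protein-centered deformation map wants. Before
alignment, coordinates are wrapped so the selection centroid lies in the
primary cell (triclinic cells handled through fractional coordinates).

The transmembrane selection is user-supplied residue ranges; when absent, a
default of Cα atoms within a ±15 Å z-slab about the phosphorus midplane of
the reference keeps the pipeline runnable. Superpositions are unweighted.

## 2D thickness maps

Per frame: phosphorus atoms are partitioned into leaflets about the
**median** z of the selection (median, not mean, because the asymmetric
distortion near the protein skews the distribution; atoms exactly at the
midplane go to the upper leaflet — a fixed tie rule so labels are
deterministic). Each leaflet's z is interpolated at the cell centers of a
regular xy grid with scipy's C1 piecewise-cubic Clough–Tocher interpolant
on a Delaunay triangulation of the (x, y) positions. Before triangulation,
points are replicated across periodic box edges into a margin of width
twice the mean nearest-neighbor spacing so the triangulation hull covers
the whole primary cell. The upper surface minus the lower surface is the
per-frame thickness field; cells where either surface is outside the hull
do not contribute to that frame.

Averaging: per-cell mean over frames within each replicate, then a
frame-count-weighted mean across replicates — algebraically identical to
pooling all frames, which is asserted in tests to 1e−9. `n_samples` records
per-cell coverage; cells defined in only some frames are averaged over
those frames rather than biased toward zero.

Grid spacing defaults to 2 Å (about one cell per lipid headgroup diameter
at a ~120 Å box); no spatial smoothing is applied beyond the interpolant
itself. The interpolant reproduces planar fields exactly (gradient
estimation run at tolerance 1e−10), so a flat leaflet yields a constant
surface regardless of point scatter — the basis of the flat-bilayer
exactness test.

Interpolating *noisy* scatter with an exact C1 interpolant can overshoot
locally where two points lie close in (x, y) with different z (lipids from
a rough leaflet can project near-coincidentally). Those overshoots are
zero-mean and average out over frames; they are why per-frame fields are
not clamped. A leaflet-label swap, by contrast, negates the field globally,
so the averaged map is required to be positive in every defined cell and a
violation raises an error.

**Thinning-well model.** Protein-induced thinning is quantified by a
least-squares fit of `T(r) = T0 − D·exp(−r²/2σ²)` (r from the protein
center) over defined cells, via `ThinningWellModel.fit()` →
`ThinningWellResults` (estimates, Jacobian-based standard errors, residual
RMS, `summary()`). The radial Gaussian is a package choice — the simplest
deformation with independent depth and width parameters — not a form taken
from the literature. Initialization: `T0` from the outer-quartile mean, `D`
from `T0 − min`, `σ` from the 30th radius percentile; parameters are
bounded non-negative.

## 3D occupancy volumes

Occupancy of a voxel is the fraction of pooled frames in which **at least
one** selected atom lies inside it (half-open voxel intervals). The binary
per-frame estimator is what makes an iso-level such as 0.6 meaningful —
"occupied in 60 % of frames"; a mean-atom-count mode (`mode="density"`) is
available for comparison. Atoms outside the grid are ignored but tallied;
if more than half of all atom-frames miss the grid, the grid is considered
misplaced and the run errors out rather than silently reporting a truncated
volume. Defaults: 1 Å voxels, grid auto-sized to the selection's bounding
box plus 5 Å. Iso-surfaces are extracted with scikit-image marching cubes
(linear interpolation along voxel edges) and written as Wavefront OBJ;
volumes as OpenDX with voxel-center origins and z-fastest ordering.

The default iso-level 0.6 is appropriate for the headgroup density of a
real bilayer; the synthetic generator places a single point particle per
lipid and is much sparser, so the shipped example uses 4 Å voxels and level
0.3.

## Structural geometry

- **Membrane normal** = the C2 symmetry axis of the ATPase dimer: the
  Kabsch rotation mapping one chain's Cα set onto its partner's must be
  within 15° of a half-turn, and its rotation axis (computed as the top
  eigenvector of the symmetrized rotation matrix, which is numerically
  stable near 180°) is the normal, anchored at the midpoint of the chain
  centroids. For synthetic membrane systems the normal is z by
  construction.
- **Helix axis**: first principal component of the ordered Cα trace,
  sign-fixed toward the C-terminus; length is the max−min extent of Cα
  projections on the axis. On ideal helices this recovers direction to
  ≲0.2° at 41 residues; short fragments with a non-integer number of turns
  bias the axis by up to ~1.5°, which is why benchmark measurements use
  full-length helices.
- **Angles**: tilt and inter-helix angles are line angles
  `arccos(|u·v|) ∈ [0°, 90°]` (axis sign never matters); the lipid-tail
  tilt is directional, `arccos(u·v) ∈ [0°, 180°]`, because head→tail
  orientation is physically meaningful.
- **Buried interface area**: Shrake–Rupley SASA with 960 golden-spiral
  points per atom, probe 1.4 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 /
  P 1.80 / Zn 1.39 Å, hydrogens ignored. Buried area is the half-sum
  convention `0.5·(SASA(A)+SASA(B)−SASA(A∪B))`, i.e. the mean of the two
  per-side ΔSASA values (which are also reported, since either per-side
  value is an equally defensible convention). The implementation is checked
  against the closed-form two-sphere spherical-cap overlap and against an
  independent Shrake–Rupley implementation with matched radii.

Angles are reported to 0.1°.

## Synthetic data generator

The generator emulates the phosphorus-atom subset of a simulated bilayer:
`n_per_leaflet` particles per leaflet placed uniformly at random, riding on
analytic surfaces `z_upper = +T0/2 − a·w(r)`, `z_lower = −T0/2 +
(1−a)·w(r)` with `w(r) = D·exp(−r²/2σ_w²)`, where `a` (asym) is the
fraction of thinning carried by the upper (cytosolic) leaflet. Particles
random-walk laterally with per-frame Gaussian steps (wrapped periodically);
z is resampled from the surface each frame plus `N(0, noise_z²)` — no
z-memory, the simplest process with the correct stationary distribution.
Frame times are k·dt from k = 1, replicate r uses RNG stream `seed + r`,
and generation is bit-deterministic per (seed, replicate). Ideal α-helix
bundles (rise 1.5 Å, radius 2.3 Å, twist 100°/residue) provide exact
ground truth for the geometry operations.

Default conditions used by the recovery studies: T0 = 40 Å, D = 8 Å,
σ_w = 15 Å, noise_z = 2 Å, step 1 Å/frame, 120 × 120 Å box — a
physiological ER-like bilayer thickness with a thinning of the magnitude a
membrane-distorting insertase produces, and headgroup z-fluctuations of
typical amplitude. The noisy recovery study uses 512 lipids/leaflet and
200 frames × 3 replicates; exactness checks use 256 lipids and 50 frames.
These sizes give sub-2 % recovery of all three well parameters while
keeping every run desk-scale.

What the generator does **not** emulate: lipid chemistry and tails,
excluded volume (particles can approach arbitrarily closely in xy, unlike
real headgroups), inter-leaflet coupling, protein–lipid interactions, and
undulation spectra. Passing recovery tests therefore demonstrates the
correctness of the mapping/fitting machinery, not the realism of any
particular membrane model.

## Degenerate inputs and tie-breaks

- Leaflet assignment requires ≥ 8 phosphorus atoms and ≥ 4 per leaflet;
  violations name the frame.
- Surface interpolation requires ≥ 4 non-collinear points; degenerate
  triangulations raise rather than extrapolate.
- In-plane alignment requires ≥ 3 masked atoms, non-collinear in xy.
- Kabsch requires ≥ 3 paired atoms and a rank-≥2 covariance; the
  reflection case is corrected to a proper rotation (det +1).
- C2 detection rejects rotations farther than 15° from 180° ("not a C2
  pair"), including the identical-chain case.
- Atoms exactly on voxel boundaries belong to the higher voxel (half-open
  intervals); atoms exactly at the leaflet midplane are upper.

## Known limitations

- Thickness maps are Eulerian (fixed grid); strongly curved membranes
  would need a curved reference surface, which is out of scope.
- The Gaussian well is radially symmetric; real insertase-induced thinning
  is anisotropic around the hydrophilic groove, so `D` and `σ` are
  effective (azimuthally averaged) parameters.
- Occupancy volumes are not time-resolved and carry no per-lipid-species
  resolution.
- The in-plane superposition assumes the membrane normal is z; tilted
  simulation setups must be pre-rotated.
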