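# Analysis inputs for `memdeform thickness` / `memdeform occupancy`.
topology: run/sim/system.pdb
trajectories:
  - run/sim/replicate_0.xtc
  - run/sim/replicate_1.xtc
  - run/sim/replicate_2.xtc

t_cut: 0.0          # ns of equilibration to discard (200 for production MD)
grid_spacing: 2.0   # A, 2D thickness-map grid
# The synthetic generator carries only one phosphorus particle per lipid,
# far sparser than a real bilayer, so the example uses coarser voxels and a
# lower iso level than the 1 A / 0.6 defaults used for production MD.
voxel: 4.0          # A, 3D occupancy voxel edge
iso_level: 0.3      # iso-occupancy level for surface extraction

# Transmembrane selection used for in-plane superposition; omit to infer
# C-alpha atoms within a 15 A z-slab about the phosphorus midplane.
tm_selection:
  chains: [A, B]
  atom_names: [CA]

fit_well: true      # fit the radial Gaussian thinning-well model
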