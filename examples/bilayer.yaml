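# Synthetic deformed-bilayer system for `memdeform simulate`.
bilayer:
  T0: 40.0          # nominal bilayer thickness, A
  D: 8.0            # thinning-well depth, A
  sigma_w: 15.0     # well lateral width, A
  asym: 0.7         # fraction of thinning carried by the upper (cytosolic) leaflet
  Lx: 120.0
  Ly: 120.0
  n_per_leaflet: 256
  noise_z: 2.0      # per-frame Gaussian z noise, A
  step_xy: 1.0      # lateral random-walk step s.d., A
  n_frames: 100
  dt: 1.0           # ns between frames
  n_replicates: 3
  seed: 42

# Optional ideal-helix bundle placed at the well center.
protein:
  helices:
    - {anchor: [55.0, 60.0, -20.0], direction: [0.0, 0.0, 1.0], n_residues: 27}
    - {anchor: [65.0, 60.0, -20.0], direction: [0.0, 0.0, 1.0], n_residues: 27}

traj_format: xtc
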