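# Full-study configuration (these are also the built-in defaults).
seed: 0

lattice:
  nx: 110            # nodes along x
  ny: 76             # node rows
  spacing: 25.0      # nm per bond; 2a = 200 nm spans 8 bonds
  bond_stiffness: 1.0     # N/m
  critical_stretch: 0.04  # bond strain at brittle break
  thickness: 100.0        # nm, energy/stress normalisation

primary_crack:
  length_nm: 750.0

loading:
  max_displacement: null   # null = derived bound (8 x critical strip opening)

sweep:
  orientations: [y, x]
  s_grid: [300, 400, 500, 600, 700, 800, 900, 1000]   # nm
  half_length_a: 100.0     # nm (crack length 2a = 200 nm)
  spacing_d: 200.0         # nm tip-to-tip ligament
  jitter: 0.0              # nm positional noise (0 = ideal pattern)

ctod:
  curves:
    nanotwinned:     {max_extension: 400.0, n_points: 9, noise_sd: 0.0}
    single_crystal:  {max_extension: 400.0, n_points: 9, noise_sd: 0.0}
  geometry: {width: 1000.0, height: 4000.0, crack_length: 400.0, mesh_refinement: 5}
  material: {youngs_modulus: 120.0, poisson_ratio: 0.3, plane: strain}
  gauge_length: 50.0       # nm, delta-5 gauge spacing

hierarchy:
  n_levels: 3
  total_mineral: 0.99
  constituents: {}         # defaults: see conchtough.hierarchy.ConstituentProps
  scale_grid: [1.0, 1.5, 2.0, 2.5, 3.0]
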