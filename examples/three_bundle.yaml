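# Three-bundle crossing phantom, SNR-matched scheme comparison.
phantom:
  geometry: three_bundle_crossing
  grid_shape: [24, 24, 24]
  voxel_size: [2.0, 2.0, 2.0]
  radius: 3.0
snr: 20
schemes:
  - {name: DSIq5b8000, kind: cartesian, method: dsi, b_max: 8000, lattice_radius: 5}
  - {name: DSIq4, kind: cartesian, method: dsi, b_max: 6400, lattice_radius: 4, n_averages: 2}
  - {name: QBI, kind: shell, method: qbi, b_max: 3000, n_directions: 257}
  - {name: DTI65, kind: shell, method: dti, b_max: 1000, n_directions: 65, n_averages: 4}
  - {name: DTI21, kind: shell, method: dti, b_max: 1000, n_directions: 21, n_averages: 3}
reference: DSIq5b8000
n_f: 5
fiber_limit: true
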