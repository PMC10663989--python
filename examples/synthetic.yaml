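# Fully synthetic end-to-end run: renders 13 gravity-deformed drops from
# known ground truth, draws a conservation-law density series, and carries
# the recovered parameters through to the lattice-theory comparison.
protein: ddx4n_1-229
seed: 11
synthetic:
  n_drops: 13
  apex_radius: 150.0        # um
  capillary_length: 293.0   # um
  pixel_size: 1.3           # um/px
  noise_sd: 0.01
  blur_radius: 1.0
  delta_rho: 97.0           # kg/m^3
  rho_alpha: 1000.2         # kg/m^3
  n_density_samples: 13
  density_noise_sd: 5.0e-4
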