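# Example configuration: all sections optional, defaults shown.
geometry:
  dendrite_radius: 0.5        # um
  total_length: 20.0          # um
  free_diffusion: 400.0       # um^2/s (fluorescein in water)
calibration:
  target_ratio: 0.05          # D_eff / D  (the 1/20 crowding factor)
  calibration_ratio: 0.035    # eps / L aspect ratio
solver:
  dx: 0.05                    # um
  bc: reflecting
simulation:
  n_particles: 10000
  base_step: 1.0e-5           # s
  adaptive_min_fraction: 0.4  # of the smallest geometric length
  sampling_period: 7.0e-4     # s (0.7 ms line period)
  rng_seed: 0
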