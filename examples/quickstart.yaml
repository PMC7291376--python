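# Small demonstration experiment: charged host-guest pair in a wide binding
# funnel; scaled-down cycle counts for a quick desk run.
seed: 2024
output_dir: scratch/quickstart
system:
  box_lengths: [4.28, 4.33, 4.33]
  host_radius: 0.3
  guest_mass: 116.0
  guest_charge: -1.0
  host_charge: -1.0
  well_depth: 4.0
  well_width: 0.2
  temperature: 300.0
  friction: 3.0
  timestep: 0.01
basins:
  bound_cutoff: 0.05
  unbound_cutoff: 1.0
resampler:
  alpha: 4.0
  d0: 0.5
  p_min: 1.0e-12
  p_max: 0.1
  merge_distance: 0.25
  max_clone_merge_per_cycle: 4
run:
  n_walkers: 48
  n_cycles_unbinding: 100
  n_cycles_rebinding: 30
  cycle_time_unbinding_ps: 20.0
  cycle_time_rebinding_ps: 100.0
  n_replicates_unbinding: 2
  n_replicates_rebinding: 2
  burn_in_cycles_unbinding: 20
  burn_in_cycles_rebinding: 5
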