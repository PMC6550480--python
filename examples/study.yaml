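# Study-scale configuration: 1 nm pores at 28% areal nanopore coverage,
# 5x5-pore supercell, 10 nm test film (set film_thickness: 50 for the
# full selective-layer thickness).
seed: 1
geometry:
  pore_diameter: 1.0        # nm
  coverage: 0.28            # areal nanopore fraction of the film face
  film_thickness: 10.0      # nm
  reservoir_depth: 1.0      # nm each side
  n_pores_y: 5
  n_pores_z: 5
occlusion:
  mode: pore_cap
  cap_fraction: 0.64
  placement_seed: 1
solver:
  voxel_size: 0.25          # nm (requested; snapped to the pore lattice)
  tolerance: 1.0e-10
  separation: film
sweep:
  mode: pore_cap
  fractions: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.64, 0.7, 0.8, 0.9, 1.0]
synth:
  true_capping: 0.64
  noise_sd_rel: 0.05
  n_replicates: 10
characterize:
  threshold_pct: 90.0
paths:
  out_dir: results/study_run
log_level: INFO
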