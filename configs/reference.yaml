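# Reference pipeline configuration: all block types with explicit defaults.
#
# Species blocks may mix measured primaries (entered directly) with
# synthetic-generator blocks whose outputs are pushed through the full
# estimation chain.  Derived summary columns (B = tau_rot/Rg^3 and
# tau_max/tau_rot) are always recomputed from the stored primaries.
seed: 1
outdir: results/reference_run
species:
  PAMAM:
    topology: {family: PAMAM, generation: 2}
    primaries:
      tau_rot_ns: 7.916
      tau_max_ns: 4.088
      rg_nm: 1.034
      nhb_intra: 10.9
      nhb_inter: 7.5
  PPI:
    topology: {family: PPI, generation: 2}
    primaries:
      tau_rot_ns: 1.074
      tau_max_ns: 0.512
      rg_nm: 0.873
      nhb_intra: 2.0
      nhb_inter: 0.0
  PCS:
    topology: {family: PCS, generation: 2}
    primaries:
      tau_rot_ns: 0.831
      tau_max_ns: 0.461
      rg_nm: 0.872
      nhb_intra: 0.0
      nhb_inter: 0.0
  # fully synthetic species: every primary is estimated from generated data
  SYNTH-G2:
    topology:
      family: generic
      core_functionality: 3
      branch_functionality: 3
      generation: 2
      spacer_beads: 1
    stress_gp:
      # Maxwell tail G ~ exp(-2t/tau_max); alternatives:
      #   target: {powerlaw: {exponent: -0.45, window_ps: [10, 1000], amplitude: 100.0}}
      #   target: {modes: [[60.0, 100.0], [40.0, 1000.0]]}
      target: {maxwell: {tau_max_ns: 0.1, g0_bar: 100.0}}
      dt_ps: 2.0
      n_frames: 1048576
      volume_nm3: 1000.0
      temperature_K: 600.0
      tail_levels: [0.01, 0.2]
    rotational:
      d_rot_per_ps: 0.01    # tau_rot = 1/(2 D) = 50 ps
      dt_ps: 0.5
      n_frames: 40000
      n_molecules: 27
    bd:
      n_molecules: 27
      spring_constant: 1.0  # kJ/mol/nm^2
      friction: 1.0         # amu/ps
      temperature_K: 600.0
      timestep_ps: 0.02
      n_steps: 40000
      coord_stride: 50
      box_nm: 40.0
    hbonds:
      n_molecules: 27
      bonds:
        - [0, 0, 0.28, 10.0]
        - [1, 2, 0.30, 15.0]
      box_nm: 16.0
      n_frames: 4
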