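# Demo pipeline config: two charged toy monomers, coarse 30-degree
# landscape, tetramer assembly with refinement, pore profiling and the
# electrophysiology side-chain.  Runs in a few seconds on one CPU.
seed: 1729
monomers:
  a:
    kind: toy
    n_tm: 8
    ecl_charges: [[ECS1, 2, 1], [ECS1, 7, -1]]
  b:
    kind: toy
    n_tm: 8
    ecl_charges: [[ECS1, 3, -1], [ECS2, 1, 1]]
energy:
  sigma: 4.7       # A
  epsilon: 2.0     # kJ/mol
  eps_r: 15.0
  cutoff: 12.0     # A
panel:
  increment: 30.0  # degrees; use 1.0 for the full landscape (~15 s)
  contact_gap: 0.5
  percentile: 10.0
assembly:
  gap: 2.0         # A between facing extracellular surfaces
  refine: true
pore:
  z_step: 0.5
  probe_threshold: 0.9
residues:
  cutoff: 6.0
  mode: surface
ephys:
  true_p_na: 1.0e-5
  true_p_cl: 5.0e-6
  true_p_li: 1.2e-5
  noise_sd_mv: 0.0
  true_papp: 2.0e-7
  noise_frac: 0.0
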