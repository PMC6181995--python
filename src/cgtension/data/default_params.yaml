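# Default feedback-model parameters (dimensionless tension units, gamma_p = 1).
# Chosen so the unperturbed system has a unique stable set point near
# gamma = 1, the stretch-relax endocytic transient decays on the ~90 s
# scale, and the perturbation-panel steady-state orderings hold.
params:
  gamma_p: 1.0    # passive tension baseline
  tau_m: 100.0    # passive membrane relaxation time, s
  k_a: 0.05       # tension <- net endocytic flux coupling
  k_e: 1.0        # CG endocytic capacity
  gamma_e: 20.0   # tension scale of direct endocytic inhibition (weak arm)
  h: 2.0          # steepness of direct endocytic inhibition
  J_x: 0.9        # exocytic capacity
  gamma_x: 1.0    # exocytic saturation tension
  tau_v: 1.0      # vinculin activation time, s (fast tension sensor)
  gamma_v: 1.0    # tension scale of vinculin activation
  n: 4.0          # steepness of vinculin activation
  tau_g: 30.0     # GBF1 membrane-pool relaxation time, s (slow arm)
  g_max: 1.0      # GBF1 recruitment ceiling
  K: 0.5          # vinculin scale of GBF1 inhibition
  m: 4.0          # steepness of GBF1 inhibition

# Default preset magnitudes for in-silico perturbations
presets:
  stretch_relax: 1.3   # areal-strain tension factor
  hypo_iso: 1.5        # hypotonic tension factor
  bfa: 2.0             # GBF1/ARF1 availability scaling (g_max x)
  dyn_tko: 1.5         # endocytic capacity scaling (k_e x)
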