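# Wild-type default configuration. Any field may be overridden; missing
# fields keep their built-in defaults. Weight overrides use keys like
# "PEI->EIP:central".
lif:
  tau_m_ms: 20.0
  v_rest_mv: -70.0
  v_thr_mv: -50.0
  v_reset_mv: -55.0
  refractory_ms: 2.0
  capacitance_nf: 0.07
nmda:
  receptor: NMDA
  decay_ms: 100.0
  reversal_mv: 0.0
gaba:
  receptor: GABA
  decay_ms: 10.0
  reversal_mv: -70.0
stimulation:
  eip_ring_suppression_na: -0.04
  p_ring_suppression_na: -0.25
  photoactivation_na: 0.20
markov:
  p_forward_to_rotation: 0.40
  p_rotation_to_forward: 0.60
  step_ms: 300.0
  rotation_speed_deg_s: 20.0
  forward_speed_mm_s: 13.0
protocol:
  condition: wildtype
  stimulus_s: 60.0
  poststimulus_s: 90.0
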