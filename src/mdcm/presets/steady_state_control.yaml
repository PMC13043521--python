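# Single steady-state control: decision family with increased
# self-excitation (C7 = 3) and balanced laterals so multistability is
# suppressed; used to probe parameter degeneracy near a fixed point.
name: steady_state_control
kind: decision
params:
  He: 3.25
  Hi: 22.0
  Ke: 10.0
  Ki: 200.0
  C1: 0.1
  C2: 0.1
  C3: 15.0
  C4: 3.0
  C5: 3.0
  C6: 0.1
  C7: 3.0
  Cee_1: 0.6
  Cei_1: 19.0
  Cee_2: 0.6
  Cei_2: 19.0
  r1: 2.0
  r2: 1.0
  tau_ampa: 0.005
  noise_sd: 0.02
stimulus:
  a: 6.0
  delta: 0.0
  t0: 0.0
  offset: 2.0
  width: 0.007
noise:
  tau: 0.005
  sd: 0.02
  seed: 0
epoch: 2.0
dt: 0.001
threshold: null
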