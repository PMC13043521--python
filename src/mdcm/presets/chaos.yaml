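# Chaotic regime: identical to period_doubling except the asymmetric
# inhibitory lateral coupling (Cei_2 = 32) and its calibrated drive.
name: chaos
kind: rate
params:
  tau_e: 0.020
  tau_i: 0.010
  C1: 14.96
  C2: 14.96
  C3: 560.0
  C4: 760.0
  C5: 200.0
  C6: 14.96
  C7: 561.02
  Cee_1: 74.80
  Cei_1: 144.0
  Cee_2: 74.80
  Cei_2: 32.0
  r1_max: 70.0
  r0: 0.0
  V_star: 25.0
  ge: 5.0
  gi: 2.0
epoch: 1.5
dt: 0.001
drive: 802.8
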