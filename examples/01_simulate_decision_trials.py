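"""Generate decision trials and summarise their psychophysics.

Simulates the bistable two-column model at four evidence-quality levels
(150 stochastic 2-s epochs each), classifies every epoch by the
first-threshold-crossing rule, and prints the psychometric/chronometric
table: accuracy should rise with evidence quality while the normalised
decision time of correct trials falls, and error decisions are slower
than correct ones.
"""

from mdcm import load_preset, psychophysics, sample_decision_trials

pre = load_preset("decision")
trials = sample_decision_trials(pre.params, (0.032, 0.064, 0.128, 0.256),
                                n_per_level=150, seed=0, a=pre.stimulus.a,
                                threshold=pre.threshold, keep_series=False)
table = psychophysics(trials)
print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print("\naccuracy = correct/(correct+error) among decided trials; "
      "ndt_* are decision times normalised by the 2 s stimulus window.")
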