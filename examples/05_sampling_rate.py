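"""Sensitivity of extrinsic recovery to the output sampling rate.

Inverts one period-doubling epoch sampled at an EEG-like 500 Hz and at
10 kHz and prints the relative error of each recovered lateral strength.
Recovery quality per rate is reported, not asserted — it depends on the
inversion settings.
"""

from mdcm import sampling_rate_experiment

out = sampling_rate_experiment("period_doubling", rates=(500.0, 10_000.0))
for rate, res in out.items():
    rel = {k: f"{v:.2e}" for k, v in res["rel_error"].items()}
    print(f"{rate:8.0f} Hz  (n={res['n_samples']:6d} samples): "
          f"relative strength errors {rel}")
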