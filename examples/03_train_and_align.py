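"""Train the toy aligner on simulated pairwise data and align held-out records.

A deliberately small run (1000 records, 15 epochs, ~2 minutes on one
CPU): expect partial coverage and high accuracy on the valid outputs;
the package's full demonstration uses 2000 records and 25 epochs.
"""

import numpy as np

from seq2msa import (
    ModelConfig,
    align_with_fallback,
    column_score,
    coverage,
    fit,
    left_justify,
    pairwise_config,
    simulate_dataset,
)

train = simulate_dataset(pairwise_config(n_records=1000, seed=1))
model = fit([(r.source, r.target) for r in train], ModelConfig(epochs=15, seed=0))
print(f"training loss: {model.loss_history[0]:.3f} -> {model.loss_history[-1]:.3f}")

test = simulate_dataset(pairwise_config(n_records=30, seed=2))
outcomes, cs_model, cs_base = [], [], []
for rec in test:
    ss = rec.truth.ungapped()
    res = align_with_fallback(ss, [model])
    outcomes.append(res)
    if res.valid:
        cs_model.append(column_score(res.msa, rec.truth).cs)
    cs_base.append(column_score(left_justify(ss), rec.truth).cs)

print(f"coverage: {coverage(outcomes).coverage:.2f} "
      f"(fraction of inputs yielding a valid alignment)")
if cs_model:
    print(f"mean column score on valid outputs: {np.mean(cs_model):.3f}")
print(f"left-justified baseline mean column score: {np.mean(cs_base):.3f}")
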