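"""Simulate true alignments under the rich indel + substitution model.

Each record pairs a set of unaligned sequences with the alignment that
actually generated them (the event history), plus the drawn parameters.
"""

from seq2msa import SimulationConfig, simulate_dataset

config = SimulationConfig(n_sequences=5, n_records=3, seed=1)
for i, rec in enumerate(simulate_dataset(config)):
    p = rec.params
    print(f"record {i}: RI={p['RI']:.4f} RD={p['RD']:.4f} AI={p['AI']:.2f} "
          f"AD={p['AD']:.2f} root={p['root_length']} tree={p['tree_length']:.4f}")
    for sid, row in zip(rec.truth.ids, rec.truth.rows):
        print(f"  {sid:>5} {row}")

# The rows above are the true alignment: ungapping row i gives leaf
# sequence i exactly, and column count grows beyond the root length only
# through insertion events.
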