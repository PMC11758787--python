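"""Naive deterministic reference aligner.

Left-justifies the input: every sequence is padded with trailing gaps to
the length of the longest one.  Exact on indel-free records and
increasingly wrong as indel events accumulate, which makes it a useful
floor for benchmarking learned aligners and for studying how alignment
error responds to indel parameters.
"""

from __future__ import annotations

from .types import GAP, Msa, SequenceSet


def left_justify(seqset: SequenceSet) -> Msa:
    width = max(len(s) for s in seqset.seqs)
    rows = [s + GAP * (width - len(s)) for s in seqset.seqs]
    return Msa(list(seqset.ids), rows, seqset.alphabet)
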