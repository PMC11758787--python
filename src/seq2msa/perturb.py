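"""Controlled corruption of alignments.

Builds synthetic ensembles of known accuracy around a true alignment by
relocating gaps: each move takes one gap character of one row and
reinserts it at a different position of the same row, so the ungapped
content (and hence validity) is preserved while shared columns are
destroyed.  Used to study certainty-based selection without a trained
aligner in the loop.
"""

from __future__ import annotations

import numpy as np

from .types import GAP, Msa


def shuffle_gaps(msa: Msa, n_moves: int, rng: np.random.Generator, max_tries: int = 100) -> Msa:
    """Return a copy of ``msa`` with ``n_moves`` random gap relocations.

    Rows keep their ungapped sequences; moves that would create an
    all-gap column are retried.  An alignment without gaps is returned
    unchanged (there is nothing to move).
    """
    rows = list(msa.rows)
    gap_rows = [i for i, r in enumerate(rows) if GAP in r]
    if not gap_rows:
        return Msa(list(msa.ids), rows, msa.alphabet)
    for _ in range(n_moves):
        for _ in range(max_tries):
            i = gap_rows[int(rng.integers(len(gap_rows)))]
            row = rows[i]
            gaps = [p for p, ch in enumerate(row) if ch == GAP]
            src = gaps[int(rng.integers(len(gaps)))]
            stripped = row[:src] + row[src + 1:]
            dst = int(rng.integers(len(stripped) + 1))
            if dst == src:
                continue
            candidate = stripped[:dst] + GAP + stripped[dst:]
            new_rows = rows[:i] + [candidate] + rows[i + 1:]
            if any(all(r[c] == GAP for r in new_rows) for c in range(len(candidate))):
                continue
            rows = new_rows
            break
    return Msa(list(msa.ids), rows, msa.alphabet)
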