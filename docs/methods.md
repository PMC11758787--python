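# Methods

This note records the models, algorithms, and design choices behind
`seq2msa`, in the order the pipeline uses them: simulation of true
alignments, sentence representations, the trainable aligner backend,
certainty-based ensemble selection, evaluation metrics, and embedding
extraction.

## Simulation of true alignments

Each simulated record is a set of unaligned sequences together with the
alignment that generated them.

**Trees.** A rooted binary topology over k leaves is grown by uniform
random joins of subtree roots. Branch lengths are i.i.d. exponential
draws rescaled so that their sum equals a total tree length drawn
uniformly from a configured range; "tree length" therefore means the sum
of branch lengths. The default range is (0.05, 0.1) substitutions per
site, i.e. closely related sequences.

**Substitutions.** DNA evolves under a general time-reversible (GTR)
model with discrete-gamma rate variation; proteins under WAG+G with the
published Whelan–Goldman exchangeabilities and frequencies embedded as
constants. The GTR default frequencies are (0.37, 0.166, 0.307, 0.158)
for T, C, A, G and the exchangeabilities (a..e) = (0.444, 0.0843, 0.116,
0.107, 0.00027) for the pairs TC, TA, TG, CA, CG with AG fixed to 1
(the REV parametrization; values characteristic of yeast intron
sequences). Published frequency vectors are rounded — this one sums to
1.001 — so the model renormalizes frequencies within a 5e-3 tolerance
and rejects anything worse. The rate matrix is scaled to one expected
substitution per site per unit branch length and exponentiated through a
single symmetric eigendecomposition. Gamma rate variation uses 4
equal-probability categories with the category-mean discretization;
shape defaults to 1.0 and is configurable (the category rates provably
average to 1, and converge to 1 individually as shape grows, recovering
the homogeneous model).

**Indels.** Insertions and deletions are simulated by a Gillespie walk
along each branch: with current length L, events arrive at rate
(RI + RD)·L per unit branch length, each being an insertion with
probability RI/(RI+RD). Event lengths follow Zipf laws P(k) ∝ k^(−a)
truncated at 50, with independent exponents AI (insertions) and AD
(deletions). Insertion position is uniform over the L+1 inter-site
slots; deletion start is uniform over sites with overhang past the end
truncated. Sites surviving a branch accumulate substitutions over their
residence time (full branch for inherited sites, remaining time for
mid-branch insertions); inserted sites draw their character from the
stationary distribution and a fresh gamma category. These positional and
scheduling conventions are the standard simulator choices; they are
documented here as this package's contract rather than asserted to be
identical to any other simulator's internals.

Every alignment column is tracked from its birth event in a global
column order, so the true alignment is the event history itself: rows
ungap to the leaf sequences by construction, and a column deleted from
every surviving lineage is dropped. A lineage deleted down to length
zero aborts the record, which is logged and re-simulated with fresh
parameters.

**Default parameter ranges** (the reference nucleotide conditions): 10
sequences, root length uniform on [32, 44], RI, RD ~ U(0, 0.05),
AI, AD ~ U(1.01, 2.0). The pairwise preset used for CPU-scale training
narrows to 2 sequences, root length [10, 20] and RI, RD ≤ 0.02. These
simulations emulate closely related sequences with realistic indel
dynamics; they do not model micro-rearrangements, selection, rate
variation along lineages, or alignment ambiguity in low-complexity
regions, so passing tests demonstrate correctness of the machinery on
this model class, not aligner performance on arbitrary empirical data.

## Sentence representations

Input schemes fold k unaligned sequences into one token sentence:
*concat* joins them with a pipe token (vocabulary: alphabet + "|");
*crisscross* interleaves characters round-robin, padding exhausted
sequences with the gap token. Output schemes serialize an alignment:
*spaces* reads it column-major one character per token (vocabulary:
alphabet + "-"); *pairs* emits one token per column (vocabulary
(A+1)^k − 1 after excluding the impossible all-gap column: 24 tokens for
two DNA sequences, 124 for three). The column-major order for *spaces*
is fixed; a row-major variant is deliberately not offered. The default
pairing is concat input with spaces output; the alternatives are opt-in.

Decoding model output never throws: it returns either the alignment or
a verdict naming the failure — token count not divisible by k, a
character mutated relative to the input sequences, a truncated row
(the decoded row is a strict prefix of its sequence), or an illegal
token (including a pipe in the output, possible because input and
output share one dictionary). Decoding trims nothing and never repairs;
the fallback and coverage machinery require crisp validity. A row that
is neither equal to nor a prefix of its sequence is classified as a
mutation.

## Aligner backend

The backend contract is `fit` / `translate` / `align_with_fallback`
over space-separated sentence files, with a shared source/target
dictionary per alphabet and reserved padding/BOS/EOS symbols outside
the biological vocabulary. Sentences are hard-limited to 1024 tokens;
longer inputs are rejected (segmenting long sequences into windows is
out of scope here).

The trainable reference model is a compact recurrent encoder–decoder
with attention, implemented in numpy on a small reverse-mode autodiff
(`seq2msa.autodiff`, gradient-checked against finite differences): a
bidirectional GRU encoder (hidden width = embed_dim per direction), a
GRU decoder whose input concatenates the previous output token's
embedding with an attention context, scaled dot-product attention over
projected encoder states, and an output projection over
[state, context, embedding]. The toy configuration (64-dim, ~2
recurrent layers' worth of parameters) trains on thousands of short
pairwise records in minutes on one CPU. The published large-transformer
configurations ("original": max-tokens 4096; "alternative": max-tokens
2048; both 16 heads / 1024-dim / 6 layers, learning rate 5e-5, 3000
warmup updates) are carried as named presets for provenance and
warm-start lineage; they share the training loop but are not
CPU-practical at full size, so none of this package's measurements
depend on them.

Training minimizes the mean per-token cross-entropy (the loss of a
position is −log P(correct token); the sentence loss is the average
over positions, so it is invariant to sentence length under a constant
per-position distribution). Batches are formed by a token budget
("max tokens", the per-update token count; it has no effect at
inference). Optimization is Adam with linear learning-rate warmup. The
toy defaults — learning rate 3e-3, 200 warmup updates, 25 epochs —
were chosen once as a configuration that reliably reaches near-zero
training loss on the pairwise preset within minutes. Everything is
seeded: two fits from the same seed produce bit-identical loss
trajectories, and decoding is deterministic.

Decoding is greedy by default; a beam width > 1 enables a simple
length-normalized beam search. Warm starting (`fit(..., warm_start=m)`)
copies the donor's parameters and requires an identical token
dictionary — transfer is only defined between models that process the
same representation. Nested "subspace" configurations (each parameter
range contained in the enclosing one) are validated by
`make_nested_subspaces`.

The fallback chain tries an ordered list of models sharing one
representation and returns the first output whose decoded verdict is
OK, recording every verdict; if all fail, the result is a failure that
counts against coverage.

## Ensemble selection by certainty

Permuting the input order changes the concat sentence and hence the
alignment, so k inputs yield up to k! alternatives per model
configuration. `generate_alternatives` samples distinct permutations
without replacement per model (requests beyond k! are clamped with a
warning), de-permutes every candidate back to canonical row order, and
keeps invalid candidates with their verdicts.

Columns are compared by residue identity: a column's key is the tuple
of 1-based residue ordinals (or gap) per row, taken in canonical input
order, so the same residue pairing matches across alignments of
different widths. The column certainty of a column of x against a set Y
is the fraction of members of Y containing an identical key; the
alignment certainty is the mean over x's columns. `select_best` drops
invalid candidates, scores each valid candidate against the other
valid candidates (invalid ones carry no alignment to compare against),
and returns the maximizer; ties break by provenance order
(configuration, then permutation), and a lone valid candidate scores
1.0 by convention. Selection is deterministic given the ensemble.

## Evaluation

The column score (CS) of an inferred alignment against the truth is the
number of shared columns (by residue-ordinal key) divided by the true
alignment's column count — the truth-normalized denominator keeps
CS ≤ 1; CS-error = 1 − CS. Comparing alignments of different sequence
sets is an argument error, never a zero score. Coverage is the fraction
of inputs for which any valid alignment was produced; failures are
excluded from mean CS (which therefore measures error on valid
alignments only) but included in coverage.

Parameter-sweep binning uses ten equal bins per axis — (1.0, 1.1) …
(1.9, 2.0) for the length exponents AI/AD and (0.000, 0.005) …
(0.045, 0.05) for the rates RI/RD — half-open except the last, with
per-cell mean score and count and empty cells flagged. `binned_trend`
summarizes an error-vs-parameter relationship as the Spearman rank
correlation of bin means against bin order.

## Embeddings

`extract` runs only the encoder over a concat sentence (the decoder is
skipped) and returns one vector per token — width 2·embed_dim, the two
GRU directions concatenated; the final encoder layer supplies the
vectors. `compress` mean-pools each sequence's token span and copies
each pipe token's vector verbatim, in sentence order (seq1, pipe1,
seq2, …, seqn), giving exactly 2n−1 blocks and d·(2n−1) entries
regardless of sequence lengths: three sequences totaling 13 nt through
a width-1024 encoder give a 1024×15 matrix compressed to 1024×5 = 5120
entries. Mean pooling makes the compression invariant to permuting
tokens within a sequence span — a deliberate loss of positional detail
in exchange for fixed size. The root-length demo fits ordinary least
squares on the flattened blocks with a 90/10 record split and reports
held-out R² and MSE; a design with all-constant features is refused.

## Problem sizes used by the checks

The shipped checks run at desk scale, chosen so the whole suite
completes in minutes while each property remains statistically
comfortable: representation round trips on 1000 simulated alignments;
the rate-vs-length trend on 5000 ten-sequence records (≥50 per bin);
selection-vs-random on 200 synthetic ensembles of six candidates;
the end-to-end run trains the toy model on 2000 pairwise records and
evaluates on 100 held-out records against the left-justified baseline.
Directional claims (error rises with indel rates; certainty selection
is at least as accurate as a random pick; warm starts dominate cold
starts) are asserted as inequalities, not magnitudes — the magnitudes
printed for the full-scale published transformers require GPU-scale
training that this package deliberately does not reproduce.

## Known limitations

* The indel scheduler's per-event conventions (uniform slots, truncated
  overhang, rate proportional to current length) are one reasonable
  convention; other simulators differ in detail.
* The toy model handles short sequences only in practice; nothing
  segments inputs beyond 1024 tokens.
* Certainty selection assumes errors across candidates are somewhat
  independent; ensembles of systematically identical mistakes will
  vote confidently for them.
* The regression demo shows that compressed embeddings carry length
  information; it is not a calibrated ancestral-length estimator.
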