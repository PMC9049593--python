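# Methods

This note documents the models, procedures and design choices behind
chemner, in the spirit of a statistical package's methods appendix. It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Data model and offset conventions

All character offsets are 0-based, half-open, and counted in Unicode code
points. Offset-annotated corpora carry per-document title and abstract
text; mention offsets are relative to their own section, never to a
concatenation. Every reader enforces *surface fidelity* — the section
text sliced at `[start, end)` must equal the annotated surface — and
reports violations (and annotations whose document id is unknown) rather
than silently dropping them, because corrupted offsets are the dominant
failure mode in distributed corpus files.

Sentence splitting uses a deliberately simple rule (split after
sentence-final punctuation followed by whitespace). Published corpora do
not document their splitters; the splitter is a pluggable function
wherever sentence ranges are consumed, and all shipped metrics are
splitter-consistent because the same splitter is used on both sides of
every comparison.

### Projecting spans onto tokens

A token overlapping a mention by at least one character is tagged as part
of the entity; the first overlapped token gets `B-`, the rest `I-`. A
mention with a boundary strictly *inside* a token cannot be represented
exactly at that tokenization; it is still tagged (by the overlap rule) but
flagged as **partial** and counted by the tokenizer metrics. An entity
split across tokens with aligned boundaries is not partial. Overlapping
mentions are an error. Invalid IOB2 in third-party files is a strict
error by default; a repair mode promoting orphan `I` to `B` is available
by flag.

## Tokenizers

The WordPiece tokenizer performs greedy longest-match-first decomposition
of each whitespace/punctuation-delimited word; continuation pieces carry
the `##` prefix and an out-of-closure word becomes a single unknown token
whose span still covers the whole word, so offset arithmetic never
breaks. Casing is preserved end to end (cased vocabularies are matched
exactly). Subword merging rebuilds word-level spans and returns a
word→subword alignment map; metrics and tagger predictions are word-level
throughout.

The rule tokenizer (whitespace split plus detachment of every punctuation
character, including hyphens) is a deterministic stand-in for
Penn-Treebank-style legacy chemical tokenizers. Parity with any specific
legacy implementation is only checkable through the external-adapter
interface, which wraps a third-party tokenizer callable and validates its
spans against the same contract.

## Corpus combination

The combined-corpus pipeline (a) strips all non-chemical label classes to
`O` (which chemical class names count is a configurable list, default
`CHEM`/`MAT`), (b) replaces purely numeric tokens with the `⟨nUm⟩`
placeholder in **both** sources and all splits (configurable off) — the
numeric predicate is digits with optional internal `.`/`,` separators,
exposed as a pattern because corpus releases differ on edge cases — (c)
re-splits the document corpus 90:10 into train/development at document
level with a seeded shuffle (a held-out test split never passes through),
and (d) shuffles the concatenated training sentences, seeded, at sentence
granularity (the model consumes sentences). Every sentence keeps a
provenance tag and the build emits a manifest of seeds and counts. The
pipeline provably conserves chemical entities and sequence lengths, and
fixed-seed builds are byte-identical — both are tested.

Unique-entity overlap between corpora is computed on surfaces normalized
by lowercasing and removing all whitespace.

## Taggers

### CRF output layer

A linear-chain CRF scores sequences with emission, transition, start and
end scores. Transitions forbidden by the BIO scheme receive a −10⁴
penalty inside the differentiable forward recursion (exp(−10⁴) underflows
to exactly zero in float64, so the partition function equals a
valid-sequences-only enumeration to machine precision while keeping
gradients finite) and hard −∞ during Viterbi decoding. `O` is tag index 0
and ties break toward the lowest index at every backtrack step, so an
all-zero score matrix decodes to all-`O`. Decoded sequences are BIO-valid
by construction; the suite asserts both properties and checks the forward
log-partition and best path against exhaustive enumeration.

### Encoders

The pretrained deep encoder is pluggable. The in-repo encoder is a tiny
randomly initialized subword-embedding encoder with the same contract, so
no download is ever required; its WordPiece closure vocabulary contains
every training word type plus all single characters as initial and
continuation pieces, so unseen words decompose into character pieces
rather than collapsing to a single unknown vector.

* **frozen_embeddings** (default): encoder parameters are frozen
  (gradient-isolated; the suite checks bit-for-bit equality after an
  optimization step) and each word's vector is the mean of its subword
  vectors. Because the frozen encoder is constant, pooled vectors are
  cached per word type, which is what makes CPU training fast. Features
  optionally concatenate char-CNN outputs and feed a two-layer
  bidirectional LSTM, then a linear projection to tag scores.
* **finetune**: all encoder parameters receive gradients and each word is
  scored from its first subword through a linear layer. Mean-pooling vs
  first-subword scoring is configurable in both modes; both are standard
  and the published systems do not document their choice.

The char-CNN embeds characters (inventory built from the training
vocabulary; index 0 is padding), convolves with kernel widths 2 and 3 (16
filters each, ReLU), and max-pools over positions. Words longer than
`max_word_len` (24) are truncated with a warning.

### Training

Negative CRF log-likelihood is minimized with Adam (learning rate 0.02,
standard betas), batch size 32, sequences bucketed by length and padded
with masks; one master seed governs initialization, shuffling and
dropout (0.1 on the BiLSTM input and output). Layers run on the
package's numpy reverse-mode autodiff engine, whose every operation is
gradient-checked against central finite differences in the test suite.
Per epoch the development set is decoded and strict entity P/R/F1 logged;
the kept checkpoint maximizes development precision among epochs with
recall strictly above the floor (85 by default), falling back to best F1
while no epoch clears the floor, with ties broken toward higher recall.
Word vocabulary and tag classes come from the training split only.

## Sliding-window inference

For sequence length L > n (n divisible by 4; default 512, the usual
pretraining limit of deep bidirectional encoders): windows of length n at
stride n/2; the first window keeps labels `[0, 3n/4)`, intermediate
windows their middle n/2, and the final window is anchored at `L − n` so
it is always full-length, discarding at least its first n/4 labels. When
n/2 does not divide L the final window overlaps its predecessor by more
than n/2; its keep-start is clamped to the previous keep-end, which
preserves the exact partition of `[0, L)` while honouring the ≥ n/4
discard (the stated rule does not cover this case; clamping is this
package's choice). Kept ranges are verified to tile `[0, L)` exhaustively
for all L ≤ 200 and n ∈ {4, 8, 12, 16}. Merged predictions are repaired
to BIO validity at seams (an orphan `I` whose predecessor is `O` or of
another class is promoted to `B`), since entities may straddle seams. No
probability averaging is performed across overlaps — labels are kept or
discarded, never mixed.

## Evaluation and selection

Scoring is micro-averaged strict entity-level P/R/F1 in percent: a true
positive requires exact boundary and class equality. Degenerate
conventions (the corpora leave them undefined): with neither predictions
nor gold entities, precision = recall = 100; with gold entities and no
predictions, both are 0; F1 is 0 when P + R = 0. Selection takes the
highest-precision candidate whose recall is *strictly* above the floor,
ties to higher recall then first listed, and raises — reporting the best
achievable recall — when no candidate qualifies.

## Synthetic corpus generator

The generator emulates the statistical structure of a mixed
organic/inorganic corpus: inorganic formula entities from an
element-symbol + stoichiometry grammar (1–3 symbols, digits 2–9),
organic-name entities from a closed morpheme grammar
(prefix + 0–2 infixes + suffix, 15% with a second word), distractor
words from a fixed inventory that includes unit-like tokens, and purely
numeric tokens. Defaults: 15% entity rate per token slot, 5% numeric
rate, 50% organic fraction, and 5% of (single-word) entities fused to the
following word without whitespace — the fused fraction mirrors the rough
share of boundary-problem entities observed in real offset-annotated
chemical corpora and gives the partial-entity metric something to find.
Documents (title = first sentence) and token-level gold are emitted
consistently; every mention passes the surface-fidelity check and the
TSV and CoNLL views re-read to identical tag sequences.

Two purpose-built fixtures support the learnability checks: a *separable*
corpus whose entity surfaces come from a closed vocabulary disjoint from
the distractors (a surface-memorizing tagger can approach perfect F1),
and a *morphology* corpus where entityhood is decided purely by a
stem+suffix rule and development sentences use held-out stems — there a
word-identity model has nothing to key on while a character-aware model
generalizes, which is exactly the contrast the char-CNN variant exists
for.

What the generator does **not** emulate: real linguistic context,
annotation noise and inter-annotator disagreement, class imbalance across
documents, long abstracts near the window limit, or the true surface
statistics of either public corpus. Passing tests therefore demonstrate
the correctness of the machinery and the learnability of the models at
desk scale, not the headline scores achievable with a pretrained encoder
on the licensed corpora.

## Problem sizes

Shipped defaults keep everything on one CPU: learnability checks train on
2,000-sentence corpora (1,800/200 and 1,200/240 splits) for 12–20 epochs
at word/hidden dimension 24; CRF-vs-enumeration checks use 200 random
instances with T ≤ 6 and K ≤ 5; the fuzzing oracles use 1,000 sentences.
These sizes are the package's chosen study conditions, adequate for the
properties being demonstrated.

## Known limitations

* The fine-tune mode's in-repo encoder is non-contextual (embeddings +
  linear); it exercises the gradient-flow contract and the CRF head, not
  transformer-grade accuracy. Plugging in a real pretrained encoder is an
  optional path outside the test surface.
* The rule tokenizer approximates, but is not, any specific legacy
  tokenizer; exact parity is only checkable via the adapter.
* The sentence splitter is intentionally naive and will over-split around
  abbreviations with trailing periods.
* Training is single-threaded numpy; it is fast at the shipped sizes but
  not intended for full-scale corpora.
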