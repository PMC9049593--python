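"""Train a frozen-embedding BiLSTM-CRF tagger and score it.

Uses a separable synthetic corpus (entity surfaces drawn from a closed
vocabulary) so a few epochs on one CPU suffice, then reports strict
entity-level precision/recall/F1 on a held-out split.  The CRF layer
guarantees every prediction is a valid BIO sequence.
"""

from chemner.evalsel import prf_from_sequences
from chemner.corpora import TaggedSequence
from chemner.synthcorpus import separable_sequences
from chemner.tagger import EncoderConfig, train_tagger

seqs = separable_sequences(1400, seed=4)
train, dev = seqs[:1200], seqs[1200:]

config = EncoderConfig(mode="frozen_embeddings", epochs=14, seed=0)
model, history = train_tagger(train, dev, config)

print("epoch  loss    dev-P   dev-R   dev-F1")
for loss, m in zip(history.losses, history.dev_metrics):
    print(f"{m['epoch']:>5}  {loss:6.3f}  {m['precision']:6.2f}  "
          f"{m['recall']:6.2f}  {m['f1']:6.2f}")

preds = [TaggedSequence(s.tokens, model.predict(s.words())) for s in dev]
prf = prf_from_sequences(dev, preds)
print(f"\nfinal dev entity scores: P={prf.precision:.2f} R={prf.recall:.2f} F1={prf.f1:.2f}")
print("(strict matching: an entity counts only if both boundaries and the")
print("class are exactly right; the kept checkpoint maximizes precision")
print("among epochs whose recall exceeds 85%.)")
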