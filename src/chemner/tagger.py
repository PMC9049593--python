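"""Sequence-labeling taggers with a constrained CRF output layer.

Two model families share the CRF head:

* ``finetune`` — a (pluggable) deep subword encoder whose parameters are
  all updated during task training; each word is scored from its first
  subword's vector through a linear layer.
* ``frozen_embeddings`` — the encoder's parameters are frozen and its
  word vectors (mean-pooled over subwords) are used as fixed features for
  a trainable two-layer bidirectional LSTM, optionally concatenated with
  character-convolution features, followed by a linear layer.

The in-repo encoder is a tiny randomly initialized subword-embedding
encoder satisfying the same contract as a pretrained transformer; loading
published pretrained weights is an optional path, never a requirement for
training or testing.  Training minimizes the negative CRF log-likelihood
with Adam, logs entity-level development P/R/F1 per epoch, and keeps the
checkpoint with the highest development precision among epochs whose
recall clears a floor (falling back to the best F1 when none does).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field

import numpy as np

from .autodiff import Tensor, concatenate
from .corpora import TaggedSequence, TokenSpan
from .crf import CRF, TagScheme
from .evalsel import prf_from_sequences
from .nn import Adam, BiLSTM, CharCNN, Embedding, Linear, Module
from .tokenizers import WordPieceVocab, wordpiece_tokenize

__all__ = ["EncoderConfig", "Tagger", "train_tagger", "predict_tags", "TrainHistory"]

UNK = "[UNK]"
PAD_CHAR = 0


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters for one tagger variant.

    mode: ``finetune`` updates every encoder parameter; ``frozen_embeddings``
    gradient-isolates the encoder and trains only the BiLSTM/char-CNN/CRF
    stack on top of it.
    """

    mode: str = "frozen_embeddings"
    use_char_cnn: bool = False
    word_dim: int = 24
    hidden: int = 24
    n_lstm_layers: int = 2
    char_dim: int = 12
    char_filters: int = 16
    char_kernels: tuple[int, ...] = (2, 3)
    max_word_len: int = 24
    dropout: float = 0.1
    lr: float = 2e-2
    epochs: int = 20
    batch_size: int = 32
    patience: int = 20
    recall_floor: float = 85.0
    subword_pool: str | None = None  # default: mean (frozen) / first (finetune)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("finetune", "frozen_embeddings"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.subword_pool not in (None, "mean", "first"):
            raise ValueError(f"unknown subword_pool {self.subword_pool!r}")

    @property
    def pool(self) -> str:
        if self.subword_pool is not None:
            return self.subword_pool
        return "mean" if self.mode == "frozen_embeddings" else "first"


class SubwordEncoder(Module):
    """Tiny pluggable stand-in for a pretrained subword encoder.

    Decomposes each word with a WordPiece vocabulary and embeds the
    subwords; word vectors are pooled per :attr:`EncoderConfig.pool`.
    Deterministic given its seed.
    """

    def __init__(self, vocab: WordPieceVocab, dim: int, rng: np.random.Generator):
        self.vocab = vocab
        self.piece_index = {p: i for i, p in enumerate(vocab.entries)}
        self.emb = Embedding(len(vocab.entries), dim, rng)
        self.dim = dim

    def subword_ids(self, word: str) -> list[int]:
        pieces = wordpiece_tokenize(word, self.vocab)
        return [self.piece_index[p.text] for p in pieces]

    def word_vector(self, word: str, pool: str) -> Tensor:
        ids = self.subword_ids(word)
        vecs = self.emb(np.array(ids, dtype=np.intp))
        if pool == "first":
            return vecs[0]
        return vecs.mean(axis=0)


class Tagger(Module):
    def __init__(
        self,
        scheme: TagScheme,
        word_vocab: list[str],
        config: EncoderConfig,
        encoder: SubwordEncoder | None = None,
    ):
        self.scheme = scheme
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.word_index = {w: i for i, w in enumerate(word_vocab)}
        wp = WordPieceVocab.from_words(word_vocab)
        self.encoder = encoder or SubwordEncoder(wp, config.word_dim, rng)
        if config.mode == "frozen_embeddings":
            self.encoder.freeze()
        # character inventory from the training vocabulary; 0 is padding
        chars = sorted({c for w in word_vocab for c in w})
        self.char_index = {c: i + 1 for i, c in enumerate(chars)}
        feat_dim = self.encoder.dim
        self.char_cnn = None
        if config.use_char_cnn:
            self.char_cnn = CharCNN(
                len(self.char_index) + 1, config.char_dim, config.char_filters,
                config.char_kernels, rng)
            feat_dim += self.char_cnn.n_out
        if config.mode == "frozen_embeddings":
            self.bilstm = BiLSTM(feat_dim, config.hidden, config.n_lstm_layers, rng)
            self.proj = Linear(self.bilstm.n_out, scheme.n_tags, rng)
        else:
            self.bilstm = None
            self.proj = Linear(feat_dim, scheme.n_tags, rng)
        self.crf = CRF(scheme, rng)
        self._train_rng = np.random.default_rng(config.seed + 1)
        self._frozen_cache: dict[str, np.ndarray] = {}
        self.training = False

    # -- feature assembly -----------------------------------------------------
    def _word_matrix(self, batch_words: list[list[str]], T: int) -> Tensor:
        """(B, T, D) word vectors, zero-padded to length T."""
        cfg = self.config
        if cfg.mode == "frozen_embeddings":
            # encoder output is constant => cache pooled vectors per word type
            rows = np.zeros((len(batch_words), T, self.encoder.dim))
            for b, words in enumerate(batch_words):
                for t, w in enumerate(words):
                    vec = self._frozen_cache.get(w)
                    if vec is None:
                        vec = self.encoder.word_vector(w, cfg.pool).data
                        self._frozen_cache[w] = vec
                    rows[b, t] = vec
            return Tensor(rows)
        parts = []
        zero = Tensor(np.zeros(self.encoder.dim))
        for words in batch_words:
            vecs = [self.encoder.word_vector(w, cfg.pool) for w in words]
            vecs += [zero] * (T - len(words))
            parts.append(concatenate([v.reshape(1, -1) for v in vecs], axis=0))
        return concatenate([p.reshape(1, T, -1) for p in parts], axis=0)

    def _char_matrix(self, batch_words: list[list[str]], T: int) -> Tensor:
        cfg = self.config
        B = len(batch_words)
        maxlen = max(cfg.char_kernels)
        for words in batch_words:
            for w in words:
                maxlen = max(maxlen, min(len(w), cfg.max_word_len))
        ids = np.zeros((B * T, maxlen), dtype=np.intp)
        for b, words in enumerate(batch_words):
            for t, w in enumerate(words):
                if len(w) > cfg.max_word_len:
                    warnings.warn(
                        f"word of length {len(w)} truncated to {cfg.max_word_len} "
                        "characters for the char-CNN")
                    w = w[: cfg.max_word_len]
                for k, ch in enumerate(w):
                    ids[b * T + t, k] = self.char_index.get(ch, 0)
        feats = self.char_cnn(ids)  # (B*T, F)
        return feats.reshape(B, T, -1)

    def emissions(self, batch_words: list[list[str]]) -> tuple[Tensor, np.ndarray]:
        """Per-word tag scores for a batch of sentences.

        Returns (emissions Tensor (B, T, K), mask (B, T)).
        """
        if not batch_words or any(len(w) == 0 for w in batch_words):
            raise ValueError("every sentence must be nonempty")
        T = max(len(w) for w in batch_words)
        mask = np.zeros((len(batch_words), T))
        for b, words in enumerate(batch_words):
            mask[b, : len(words)] = 1.0
        x = self._word_matrix(batch_words, T)
        if self.char_cnn is not None:
            x = concatenate([x, self._char_matrix(batch_words, T)], axis=2)
        if self.bilstm is not None:
            x = self._dropout(x)
            h = self.bilstm(x.swapaxes(0, 1), mask.T).swapaxes(0, 1)
            h = self._dropout(h)
        else:
            h = self._dropout(x)
        return self.proj(h), mask

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0.0:
            return x
        keep = (self._train_rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    # -- inference ------------------------------------------------------------
    def predict(self, words: list[str]) -> list[str]:
        """Viterbi tags for one sentence; always BIO-valid."""
        if not words:
            return []
        self.training = False
        em, _ = self.emissions([list(words)])
        path = self.crf.viterbi(em.data[0])
        return self.scheme.decode(path)

    def invalidate_cache(self):
        self._frozen_cache.clear()

    # -- persistence ----------------------------------------------------------
    def save(self, weights_path, config_path) -> None:
        np.savez(weights_path, **{f"p{i}": p.data for i, p in enumerate(self.parameters())})
        meta = {
            "classes": list(self.scheme.classes),
            "word_vocab": [w for w, _ in sorted(self.word_index.items(), key=lambda kv: kv[1])],
            "config": asdict(self.config),
        }
        with open(config_path, "w", encoding="utf-8") as fh:
            json.dump(meta, fh, ensure_ascii=False, indent=2)

    @classmethod
    def load(cls, weights_path, config_path) -> "Tagger":
        with open(config_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        cfg = meta["config"]
        cfg["char_kernels"] = tuple(cfg["char_kernels"])
        config = EncoderConfig(**cfg)
        tagger = cls(TagScheme(tuple(meta["classes"])), meta["word_vocab"], config)
        data = np.load(weights_path)
        for i, p in enumerate(tagger.parameters()):
            p.data[...] = data[f"p{i}"]
        tagger.invalidate_cache()
        return tagger


@dataclass
class TrainHistory:
    losses: list[float] = field(default_factory=list)
    dev_metrics: list[dict] = field(default_factory=list)
    best_epoch: int = -1


def train_tagger(
    train_seqs: list[TaggedSequence],
    dev_seqs: list[TaggedSequence],
    config: EncoderConfig,
) -> tuple[Tagger, TrainHistory]:
    """Train a tagger; reproducible under a fixed config seed.

    The word vocabulary and tag classes are built from the training split
    only.  Per epoch the mean training loss and the development entity
    P/R/F1 are recorded; the returned model carries the parameters of the
    best epoch under the precision-with-recall-floor selection rule.
    """
    if not train_seqs:
        raise ValueError("empty training corpus")
    if not dev_seqs:
        raise ValueError("empty development corpus")
    classes = sorted({t[2:] for s in train_seqs for t in s.tags if t != "O"})
    if not classes:
        warnings.warn("training corpus contains no entities; proceeding anyway")
        classes = ["CHEM"]
    scheme = TagScheme(tuple(classes))
    vocab = sorted({w for s in train_seqs for w in s.words()}) + [UNK]
    tagger = Tagger(scheme, vocab, config)
    params = tagger.trainable_parameters()
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 2)
    history = TrainHistory()
    best_key = None
    best_state = None

    encoded = [
        (s.words(), scheme.encode(s.tags)) for s in train_seqs
    ]
    for epoch in range(config.epochs):
        order = rng.permutation(len(encoded))
        # bucket by length to limit padding waste, preserving shuffle inside buckets
        order = sorted(order, key=lambda i: len(encoded[i][0]) // 4)
        total_loss = 0.0
        n_sent = 0
        tagger.training = True
        for lo in range(0, len(order), config.batch_size):
            batch = [encoded[i] for i in order[lo : lo + config.batch_size]]
            words = [b[0] for b in batch]
            T = max(len(w) for w in words)
            tags = np.zeros((len(batch), T), dtype=np.intp)
            for b, (_, tg) in enumerate(batch):
                tags[b, : len(tg)] = tg
            em, mask = tagger.emissions(words)
            ll = tagger.crf.log_likelihood(em, tags, mask)
            loss = -ll / float(len(batch))
            opt.zero_grad()
            loss.backward()
            opt.step()
            total_loss += float(loss.data) * len(batch)
            n_sent += len(batch)
        history.losses.append(total_loss / n_sent)

        tagger.training = False
        preds = [
            TaggedSequence(s.tokens, tagger.predict(s.words())) for s in dev_seqs
        ]
        prf = prf_from_sequences(dev_seqs, preds)
        history.dev_metrics.append(
            {"epoch": epoch, "precision": prf.precision, "recall": prf.recall, "f1": prf.f1}
        )
        meets = prf.recall > config.recall_floor
        key = (1 if meets else 0, prf.precision if meets else prf.f1, prf.recall)
        if best_key is None or key > best_key:
            best_key = key
            best_state = [p.data.copy() for p in tagger.parameters()]
            history.best_epoch = epoch
        elif epoch - history.best_epoch >= config.patience:
            break

    if best_state is not None:
        for p, d in zip(tagger.parameters(), best_state):
            p.data[...] = d
        tagger.invalidate_cache()
    return tagger, history


def predict_tags(tagger: Tagger, words: list[str]) -> TaggedSequence:
    """Viterbi-decode one sentence into a TaggedSequence."""
    words = list(words)
    tags = tagger.predict(words)
    spans = []
    pos = 0
    for w in words:
        spans.append(TokenSpan(w, pos, pos + len(w)))
        pos += len(w) + 1
    return TaggedSequence(spans, tags)
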