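"""Tagger training, determinism, gradient isolation and prediction."""

import numpy as np
import pytest

from chemner.corpora import validate_bio
from chemner.synthcorpus import separable_sequences
from chemner.tagger import EncoderConfig, Tagger, predict_tags, train_tagger

from conftest import make_seq


@pytest.fixture(scope="module")
def tiny_model():
    """A model memorizing a 24-sentence separable corpus (shared across tests)."""
    train = separable_sequences(24, seed=1)
    cfg = EncoderConfig(epochs=90, seed=0, dropout=0.0, patience=200)
    model, history = train_tagger(train, train, cfg)
    return model, history, train


class TestEncoding:
    def test_emissions_deterministic_given_seed(self):
        cfg = EncoderConfig(seed=5)
        words = ["TiO2", "was", "grown"]
        a = _fresh_tagger(cfg).emissions([words])[0].data
        b = _fresh_tagger(cfg).emissions([words])[0].data
        np.testing.assert_array_equal(a, b)

    def test_char_cnn_changes_width_not_length(self):
        words = ["TiO2", "was", "grown"]
        plain = _fresh_tagger(EncoderConfig(seed=0))
        cnn = _fresh_tagger(EncoderConfig(seed=0, use_char_cnn=True))
        ep, _ = plain.emissions([words])
        ec, _ = cnn.emissions([words])
        assert ep.shape == ec.shape  # same (B, T, K) after projection
        assert cnn.char_cnn is not None and plain.char_cnn is None
        # the BiLSTM consumes wider features when char-CNN is on
        assert cnn.bilstm.layers[0][0].w.shape[0] > plain.bilstm.layers[0][0].w.shape[0]

    def test_long_word_truncated_with_warning(self):
        tagger = _fresh_tagger(EncoderConfig(seed=0, use_char_cnn=True, max_word_len=8))
        with pytest.warns(UserWarning, match="truncated"):
            tagger.emissions([["x" * 30, "ok"]])

    def test_empty_sentence_rejected(self):
        with pytest.raises(ValueError):
            _fresh_tagger(EncoderConfig(seed=0)).emissions([[]])


class TestGradientIsolation:
    def _one_step(self, mode):
        train = separable_sequences(8, seed=3)
        cfg = EncoderConfig(mode=mode, epochs=1, seed=0, dropout=0.0)
        from chemner.crf import TagScheme
        from chemner.nn import Adam

        vocab = sorted({w for s in train for w in s.words()}) + ["[UNK]"]
        tagger = Tagger(TagScheme(("CHEM",)), vocab, cfg)
        before = [p.data.copy() for p in tagger.encoder.parameters()]
        opt = Adam(tagger.trainable_parameters(), lr=1e-2)
        words = [s.words() for s in train[:4]]
        tags = np.zeros((4, max(len(w) for w in words)), dtype=np.intp)
        for b, s in enumerate(train[:4]):
            tags[b, : len(s.tags)] = tagger.scheme.encode(s.tags)
        em, mask = tagger.emissions(words)
        loss = -tagger.crf.log_likelihood(em, tags, mask)
        loss.backward()
        opt.step()
        after = [p.data for p in tagger.encoder.parameters()]
        return before, after

    def test_frozen_mode_never_touches_encoder(self):
        before, after = self._one_step("frozen_embeddings")
        for b, a in zip(before, after):
            assert np.array_equal(b, a)  # bit-for-bit

    def test_finetune_mode_updates_encoder(self):
        before, after = self._one_step("finetune")
        assert any(not np.array_equal(b, a) for b, a in zip(before, after))


class TestTraining:
    def test_loss_decreases_over_first_epochs(self, tiny_model):
        _, history, _ = tiny_model
        assert history.losses[2] < history.losses[0] * 1.01

    def test_memorizes_training_sentences(self, tiny_model):
        model, _, train = tiny_model
        hits = sum(model.predict(s.words()) == s.tags for s in train)
        assert hits >= len(train) - 1

    def test_reproducible_under_fixed_seed(self):
        train = separable_sequences(12, seed=2)
        cfg = EncoderConfig(epochs=2, seed=7)
        m1, h1 = train_tagger(train, train, cfg)
        m2, h2 = train_tagger(train, train, cfg)
        assert h1.losses == h2.losses
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_empty_dev_set_rejected(self):
        train = separable_sequences(4, seed=0)
        with pytest.raises(ValueError, match="development"):
            train_tagger(train, [], EncoderConfig(epochs=1))

    def test_no_entity_corpus_warns_but_proceeds(self):
        seqs = [make_seq(["just", "words"], ["O", "O"])] * 4
        with pytest.warns(UserWarning, match="no entities"):
            model, _ = train_tagger(seqs, seqs, EncoderConfig(epochs=1, seed=0))
        assert model.predict(["just", "words"]) == ["O", "O"]


class TestPrediction:
    def test_prediction_matches_gold_on_memorized_sentence(self, tiny_model):
        model, _, train = tiny_model
        seq = predict_tags(model, train[0].words())
        assert len(seq.tokens) == len(train[0].tokens)

    def test_oov_sentence_output_is_bio_valid(self, tiny_model):
        model, _, _ = tiny_model
        tags = model.predict(["zzzq", "qqzz", "zzqq"])
        validate_bio(tags)

    def test_idempotent(self, tiny_model):
        model, _, _ = tiny_model
        words = ["water", "TiO2", "grown"]
        assert model.predict(words) == model.predict(words)

    def test_empty_input_empty_output(self, tiny_model):
        model, _, _ = tiny_model
        assert model.predict([]) == []

    def test_save_load_roundtrip_predicts_identically(self, tiny_model, tmp_path):
        model, _, train = tiny_model
        model.save(tmp_path / "w.npz", tmp_path / "c.json")
        loaded = Tagger.load(tmp_path / "w.npz", tmp_path / "c.json")
        for s in train[:5]:
            assert loaded.predict(s.words()) == model.predict(s.words())


def _fresh_tagger(cfg):
    from chemner.crf import TagScheme

    vocab = ["TiO2", "was", "grown", "ok", "x" * 30, "[UNK]"]
    return Tagger(TagScheme(("CHEM",)), vocab, cfg)
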