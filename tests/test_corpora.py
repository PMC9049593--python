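"""Corpus data model, readers/writers and span/BIO conversions."""

import random

import pytest

from chemner.corpora import (
    CorpusReadError,
    Document,
    EntityMention,
    TaggedSequence,
    TokenSpan,
    bio_to_spans,
    entity_token_spans,
    read_chemdner_corpus,
    read_conll,
    read_matscholar_corpus,
    repair_bio,
    spans_to_bio,
    split_sentences,
    validate_bio,
    write_chemdner_corpus,
    write_conll,
    write_matscholar_corpus,
)

from conftest import make_seq, random_bio_tags, spans_from_words


class TestChemdnerReader:
    def test_reads_documents_and_attaches_mentions(self, tiny_documents):
        result = read_chemdner_corpus(*tiny_documents)
        docs = {d.doc_id: d for d in result.documents}
        assert len(docs) == 2
        d1 = docs["d1"]
        assert d1.title == "TiO2 films"
        assert len(d1.mentions) == 2
        assert not result.surface_mismatches and not result.orphan_annotations
        # surface fidelity: slicing the section text reproduces the surface
        for m in d1.mentions:
            assert d1.section_text(m.section)[m.start : m.end] == m.surface

    def test_empty_annotations_give_zero_mentions(self, tiny_documents, tmp_path):
        empty = tmp_path / "none.tsv"
        empty.write_text("")
        result = read_chemdner_corpus(tiny_documents[0], empty)
        assert all(not d.mentions for d in result.documents)

    def test_surface_mismatch_is_reported_not_dropped(self, tmp_path):
        (tmp_path / "a.tsv").write_text("d1\tTiO2 films\tabc.\n")
        (tmp_path / "m.tsv").write_text("d1\tT\t0\t4\tZnO2\tCHEM\n")
        result = read_chemdner_corpus(tmp_path / "a.tsv", tmp_path / "m.tsv")
        assert len(result.surface_mismatches) == 1
        assert len(result.documents[0].mentions) == 1  # still attached

    def test_orphan_annotation_reported(self, tmp_path):
        (tmp_path / "a.tsv").write_text("d1\tt\ta.\n")
        (tmp_path / "m.tsv").write_text("ghost\tT\t0\t1\tt\tCHEM\n")
        result = read_chemdner_corpus(tmp_path / "a.tsv", tmp_path / "m.tsv")
        assert result.orphan_annotations[0][0] == "ghost"

    def test_malformed_row_names_line_number(self, tmp_path):
        (tmp_path / "a.tsv").write_text("d1\tonly-two-fields\n")
        (tmp_path / "m.tsv").write_text("")
        with pytest.raises(CorpusReadError, match=":1:"):
            read_chemdner_corpus(tmp_path / "a.tsv", tmp_path / "m.tsv")

    def test_roundtrip_write_read(self, tiny_documents, tmp_path):
        result = read_chemdner_corpus(*tiny_documents)
        write_chemdner_corpus(result.documents, tmp_path / "a2.tsv", tmp_path / "m2.tsv")
        again = read_chemdner_corpus(tmp_path / "a2.tsv", tmp_path / "m2.tsv")
        assert again.documents == result.documents


class TestMatscholarReader:
    def test_reads_tagged_sequences(self, tmp_path):
        p = tmp_path / "ms.json"
        write_matscholar_corpus(
            [make_seq(["GaN", "is", "grown"], ["B-MAT", "O", "O"])], p)
        seqs = read_matscholar_corpus(p)
        assert len(seqs) == 1
        assert seqs[0].tags == ["B-MAT", "O", "O"]
        assert len(entity_token_spans(seqs[0].tags)) == 1

    def test_invalid_bio_raises_with_sentence_index(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('[{"tokens": ["a", "b"], "tags": ["O", "I-MAT"]}]')
        with pytest.raises(CorpusReadError, match="sentence 0"):
            read_matscholar_corpus(p)
        # repair mode promotes the orphan I to B
        assert read_matscholar_corpus(p, repair=True)[0].tags == ["O", "B-MAT"]

    def test_length_mismatch_raises(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('[{"tokens": ["a"], "tags": ["O", "O"]}]')
        with pytest.raises(CorpusReadError, match="1 tokens but 2 tags"):
            read_matscholar_corpus(p)


class TestSpanBioConversion:
    def test_aligned_mention_tagged_b(self):
        text = "Ser 845"
        tokens = spans_from_words(["Ser", "845"])
        seq, partial = spans_to_bio(text, tokens, [EntityMention("A", 0, 3, "Ser", "CHEM")])
        assert seq.tags == ["B-CHEM", "O"]
        assert partial == []

    def test_interior_boundary_flags_partial_but_still_tags(self):
        """An entity fused into a larger token is tagged by overlap and
        reported as partial (exact boundaries are unrecoverable)."""
        text = "Ser845"
        tokens = [TokenSpan("Ser845", 0, 6)]
        seq, partial = spans_to_bio(text, tokens, [EntityMention("A", 0, 3, "Ser", "CHEM")])
        assert seq.tags == ["B-CHEM"]
        assert len(partial) == 1

    def test_multi_token_mention_gets_b_then_i(self):
        text = "acetic acid here"
        tokens = spans_from_words(["acetic", "acid", "here"])
        seq, _ = spans_to_bio(text, tokens, [EntityMention("A", 0, 11, "acetic acid", "CHEM")])
        assert seq.tags == ["B-CHEM", "I-CHEM", "O"]

    def test_no_mentions_all_o(self):
        seq, partial = spans_to_bio("a b", spans_from_words(["a", "b"]), [])
        assert seq.tags == ["O", "O"] and partial == []

    def test_overlapping_mentions_raise(self):
        tokens = spans_from_words(["abcdef"])
        ms = [EntityMention("A", 0, 4, "abcd", "CHEM"), EntityMention("A", 2, 6, "cdef", "CHEM")]
        with pytest.raises(ValueError, match="overlap"):
            spans_to_bio("abcdef", tokens, ms)

    def test_roundtrip_identity_on_aligned_mentions(self):
        text = "TiO2 and acetic acid ."
        tokens = spans_from_words(["TiO2", "and", "acetic", "acid", "."])
        mentions = [
            EntityMention("A", 0, 4, "TiO2", "CHEM"),
            EntityMention("A", 9, 20, "acetic acid", "CHEM"),
        ]
        seq, partial = spans_to_bio(text, tokens, mentions)
        assert partial == []
        back = bio_to_spans(seq, text)
        assert [(m.start, m.end, m.surface) for m in back] == [
            (m.start, m.end, m.surface) for m in mentions]

    def test_bio_to_spans_matches_run_scanner_on_random_sequences(self):
        """Oracle: a linear scan enumerating maximal B/I runs."""
        rng = random.Random(123)
        for _ in range(200):
            n = rng.randint(0, 12)
            tags = random_bio_tags(rng, n)
            # oracle scan
            expect = []
            i = 0
            while i < n:
                if tags[i].startswith("B-"):
                    cls = tags[i][2:]
                    j = i + 1
                    while j < n and tags[j] == f"I-{cls}":
                        j += 1
                    expect.append((i, j, cls))
                    i = j
                else:
                    i += 1
            assert entity_token_spans(tags) == expect

    def test_invalid_bio_rejected(self):
        with pytest.raises(ValueError):
            validate_bio(["O", "I-CHEM"])
        with pytest.raises(ValueError):
            validate_bio(["I-CHEM"])
        with pytest.raises(ValueError):
            validate_bio(["B-CHEM", "I-MAT"])
        assert repair_bio(["O", "I-CHEM", "I-CHEM"]) == ["O", "B-CHEM", "I-CHEM"]


class TestConll:
    def test_writes_token_tag_lines(self, tmp_path):
        p = tmp_path / "x.conll"
        write_conll([make_seq(["a", "b", "c"], ["O", "B-CHEM", "O"])], p)
        assert p.read_text() == "a O\nb B-CHEM\nc O\n\n"

    def test_roundtrip_is_byte_identical(self, tmp_path):
        rng = random.Random(5)
        seqs = []
        for _ in range(100):
            n = rng.randint(1, 9)
            words = [f"w{rng.randint(0, 50)}" for _ in range(n)]
            seqs.append(make_seq(words, random_bio_tags(rng, n)))
        p1, p2 = tmp_path / "a.conll", tmp_path / "b.conll"
        write_conll(seqs, p1)
        write_conll(read_conll(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_windows_line_endings_parse_identically(self, tmp_path):
        unix = tmp_path / "u.conll"
        dos = tmp_path / "d.conll"
        content = "a O\nb B-CHEM\n\n"
        unix.write_text(content)
        dos.write_bytes(content.replace("\n", "\r\n").encode())
        assert [s.tags for s in read_conll(unix)] == [s.tags for s in read_conll(dos)]

    def test_ragged_line_raises_with_line_number(self, tmp_path):
        p = tmp_path / "bad.conll"
        p.write_text("a O\nb\n")
        with pytest.raises(CorpusReadError, match=":2:"):
            read_conll(p)


class TestSentencesAndTypes:
    def test_split_sentences_on_final_punctuation(self):
        text = "We grew TiO2. It was pure! Was it?"
        parts = [text[a:b] for a, b in split_sentences(text)]
        assert parts == ["We grew TiO2.", "It was pure!", "Was it?"]

    def test_split_sentences_empty_text(self):
        assert split_sentences("") == []

    def test_document_requires_id_and_mention_requires_span(self):
        with pytest.raises(ValueError):
            Document("", "t", "a")
        with pytest.raises(ValueError):
            EntityMention("T", 3, 3, "x", "CHEM")
        with pytest.raises(ValueError):
            EntityMention("X", 0, 1, "x", "CHEM")

    def test_tagged_sequence_length_mismatch(self):
        with pytest.raises(ValueError):
            TaggedSequence(spans_from_words(["a"]), ["O", "O"])
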