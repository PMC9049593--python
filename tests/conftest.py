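import random

import pytest

from chemner.corpora import TaggedSequence, TokenSpan


def spans_from_words(words):
    out = []
    pos = 0
    for w in words:
        out.append(TokenSpan(w, pos, pos + len(w)))
        pos += len(w) + 1
    return out


def make_seq(words, tags, provenance=None):
    return TaggedSequence(spans_from_words(words), list(tags), provenance=provenance)


def random_bio_tags(rng: random.Random, n: int, classes=("CHEM", "MAT")):
    """A uniformly-sampled valid IOB2 sequence."""
    tags = []
    prev_cls = None
    for _ in range(n):
        r = rng.random()
        if prev_cls is not None and r < 0.3:
            tags.append(f"I-{prev_cls}")
            continue
        if r < 0.6:
            tags.append("O")
            prev_cls = None
        else:
            prev_cls = rng.choice(classes)
            tags.append(f"B-{prev_cls}")
    return tags


@pytest.fixture
def tiny_documents(tmp_path):
    """A two-document offset-annotated corpus written to TSV files."""
    abstracts = tmp_path / "abstracts.tsv"
    annotations = tmp_path / "annotations.tsv"
    abstracts.write_text(
        "d1\tTiO2 films\tWe grew TiO2. It was pure.\n"
        "d2\tWater study\tmethanol and 450 K were used.\n",
        encoding="utf-8",
    )
    annotations.write_text(
        "d1\tT\t0\t4\tTiO2\tCHEM\n"
        "d1\tA\t8\t12\tTiO2\tCHEM\n"
        "d2\tA\t0\t8\tmethanol\tCHEM\n",
        encoding="utf-8",
    )
    return abstracts, annotations
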