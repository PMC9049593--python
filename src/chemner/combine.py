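"""Construction of a combined organic+inorganic training corpus.

The combination pipeline takes an offset-annotated abstract corpus
(organic-leaning, CHEMDNER-style) and a token-level IOB2 corpus
(inorganic-leaning, Matscholar-style), strips non-chemical label classes,
replaces purely numeric tokens with a placeholder, re-splits the abstract
corpus 90:10 into train/development at document level, concatenates, and
shuffles the training sentences so a model sees both sources evenly.
It also provides the normalized unique-entity overlap statistics used to
quantify how dissimilar two corpora are.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

from .corpora import (
    Document,
    TaggedSequence,
    TokenSpan,
    entity_token_spans,
    spans_to_bio,
    split_sentences,
    validate_bio,
)
from .tokenizers import rule_tokenize

__all__ = [
    "NUM_TOKEN",
    "DEFAULT_NUMERIC_PATTERN",
    "normalize_entity_string",
    "unique_entity_stats",
    "replace_numeric_tokens",
    "strip_nonchemical_labels",
    "resplit_train_dev",
    "documents_to_sequences",
    "build_combined_corpus",
    "CombinedCorpus",
]

#: Placeholder substituted for purely numeric tokens.
NUM_TOKEN = "⟨nUm⟩"

#: A token "consisting of only numbers": digits, optionally with internal
#: '.' or ',' separators.  Exposed so callers can narrow or widen the rule.
DEFAULT_NUMERIC_PATTERN = re.compile(r"\d+(?:[.,]\d+)*")


def normalize_entity_string(surface: str) -> str:
    """Lowercase and remove all whitespace characters."""
    return "".join(surface.lower().split())


def unique_entity_stats(
    corpus_a_surfaces: Iterable[str], corpus_b_surfaces: Iterable[str]
) -> tuple[int, int, int]:
    """Sizes of the normalized unique-entity sets and their intersection."""
    a = {normalize_entity_string(s) for s in corpus_a_surfaces}
    b = {normalize_entity_string(s) for s in corpus_b_surfaces}
    return len(a), len(b), len(a & b)


def replace_numeric_tokens(
    seq: TaggedSequence, pattern: re.Pattern = DEFAULT_NUMERIC_PATTERN
) -> TaggedSequence:
    """Replace each purely numeric token surface with ⟨nUm⟩.

    Tags, token count and token spans are unchanged; only surfaces mutate.
    """
    tokens = [
        TokenSpan(NUM_TOKEN, t.start, t.end) if pattern.fullmatch(t.text) else t
        for t in seq.tokens
    ]
    return TaggedSequence(tokens, list(seq.tags), provenance=seq.provenance)


def strip_nonchemical_labels(
    seq: TaggedSequence,
    chemical_classes: Iterable[str],
    known_classes: Iterable[str] | None = None,
) -> TaggedSequence:
    """Keep chemical-class tags; all other B-/I- tags become O.

    When ``known_classes`` is given, any tag class outside
    ``chemical_classes ∪ known_classes`` raises, listing the offenders.
    """
    chemical = set(chemical_classes)
    present = {t[2:] for t in seq.tags if t != "O"}
    if known_classes is not None:
        unknown = sorted(present - chemical - set(known_classes))
        if unknown:
            raise ValueError(f"unknown tag classes: {unknown}")
    tags = [t if t != "O" and t[2:] in chemical else "O" for t in seq.tags]
    validate_bio(tags)
    return TaggedSequence(list(seq.tokens), tags, provenance=seq.provenance)


def resplit_train_dev(
    documents: list, ratio: float = 0.9, seed: int = 0
) -> tuple[list, list]:
    """Seeded random document-level partition into train and development.

    ``|train|`` is ``round(ratio * n)``, i.e. within one document of the
    exact ratio.  The same seed always yields the same split; a held-out
    test split should never pass through here.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if len(documents) < 10:
        raise ValueError(f"need at least 10 documents to resplit, got {len(documents)}")
    order = list(documents)
    random.Random(seed).shuffle(order)
    n_train = round(ratio * len(order))
    return order[:n_train], order[n_train:]


def documents_to_sequences(
    documents: Iterable[Document],
    tokenizer: Callable[[str], list[TokenSpan]] = rule_tokenize,
    label: str | None = None,
    provenance: str | None = None,
) -> list[TaggedSequence]:
    """Sentence-split, tokenize and BIO-project an offset-annotated corpus.

    ``label`` overrides every mention's class (useful for collapsing an
    annotation taxonomy onto a single chemical class); by default classes
    are kept as annotated.
    """
    out = []
    for doc in documents:
        for section in ("T", "A"):
            text = doc.section_text(section)
            if not text:
                continue
            mentions = [m for m in doc.mentions if m.section == section]
            for s_start, s_end in split_sentences(text):
                tokens = [
                    TokenSpan(t.text, t.start + s_start, t.end + s_start)
                    for t in tokenizer(text[s_start:s_end])
                ]
                in_sent = [m for m in mentions if m.start >= s_start and m.end <= s_end]
                if label is not None:
                    in_sent = [
                        type(m)(m.section, m.start, m.end, m.surface, label)
                        for m in in_sent
                    ]
                seq, _partial = spans_to_bio(text, tokens, in_sent)
                seq.provenance = provenance
                out.append(seq)
    return out


@dataclass
class CombinedCorpus:
    train: list[TaggedSequence]
    dev: list[TaggedSequence]
    manifest: dict = field(default_factory=dict)


def build_combined_corpus(
    chemdner_docs: list[Document],
    matscholar_seqs: list[TaggedSequence],
    seed: int,
    chemical_classes: Iterable[str] = ("CHEM", "MAT"),
    matscholar_dev_seqs: list[TaggedSequence] | None = None,
    tokenizer: Callable[[str], list[TokenSpan]] = rule_tokenize,
    replace_numbers: bool = True,
    ratio: float = 0.9,
) -> CombinedCorpus:
    """Build the combined corpus from both sources.

    Pipeline: project/validate both sources to chemical-only BIO →
    replace numeric tokens in both → re-split the document corpus 90:10
    at document level → concatenate training portions → seeded shuffle of
    training sentences.  Each sentence keeps a provenance tag naming its
    source corpus.
    """
    chemical = tuple(chemical_classes)

    def prep(seqs: list[TaggedSequence], prov: str) -> list[TaggedSequence]:
        out = []
        for s in seqs:
            s = strip_nonchemical_labels(s, chemical)
            if replace_numbers:
                s = replace_numeric_tokens(s)
            s.provenance = prov
            out.append(s)
        return out

    train_docs, dev_docs = resplit_train_dev(chemdner_docs, ratio=ratio, seed=seed)
    cd_train = prep(documents_to_sequences(train_docs, tokenizer), "chemdner")
    cd_dev = prep(documents_to_sequences(dev_docs, tokenizer), "chemdner")
    ms_train = prep(matscholar_seqs, "matscholar")
    ms_dev = prep(matscholar_dev_seqs or [], "matscholar")

    train = cd_train + ms_train
    random.Random(seed + 1).shuffle(train)
    dev = cd_dev + ms_dev

    def n_entities(seqs):
        return sum(len(entity_token_spans(s.tags)) for s in seqs)

    manifest = {
        "seed": seed,
        "ratio": ratio,
        "chemical_classes": list(chemical),
        "replace_numbers": replace_numbers,
        "n_train_sentences": len(train),
        "n_dev_sentences": len(dev),
        "n_train_entities": n_entities(train),
        "n_dev_entities": n_entities(dev),
        "provenance_counts": {
            "train": {
                "chemdner": sum(s.provenance == "chemdner" for s in train),
                "matscholar": sum(s.provenance == "matscholar" for s in train),
            }
        },
    }
    return CombinedCorpus(train=train, dev=dev, manifest=manifest)
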