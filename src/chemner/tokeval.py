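"""Tokenizer-quality metrics.

Two complementary measures of tokenizer fitness for chemical NER:

* the number of *partial chemical entities* — gold mentions with at least
  one boundary strictly inside a token, which no exact-boundary tagger can
  recover at that tokenization (under-tokenization);
* the maximum tokenized sentence length and the full length histogram
  (over-tokenization).

Metrics are computed at word level; for a WordPiece tokenizer the caller
is expected to merge subwords first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Iterable

from .corpora import Document, EntityMention, TokenSpan, split_sentences

__all__ = [
    "TokenizerReport",
    "count_partial_entities",
    "is_partial",
    "max_sequence_length",
    "tokenizer_report",
]


@dataclass(frozen=True)
class TokenizerReport:
    partial_entity_count: int
    longest_sequence: int
    length_histogram: dict[int, int]

    def __post_init__(self):
        if self.length_histogram:
            assert self.longest_sequence == max(self.length_histogram)

    @property
    def n_sentences(self) -> int:
        return sum(self.length_histogram.values())

    def to_json(self) -> str:
        return json.dumps(
            {
                "partial_entity_count": self.partial_entity_count,
                "longest_sequence": self.longest_sequence,
                "length_histogram": {str(k): v for k, v in sorted(self.length_histogram.items())},
            },
            indent=2,
        )

    def histogram_tsv(self) -> str:
        lines = [f"{k}\t{v}" for k, v in sorted(self.length_histogram.items())]
        return "\n".join(lines) + "\n"


def is_partial(mention: EntityMention, tokens: list[TokenSpan]) -> bool:
    """True when a mention boundary falls strictly inside some token.

    A mention split across several tokens with aligned boundaries is NOT
    partial; only strict interior boundaries count.
    """
    return any(
        t.start < mention.start < t.end or t.start < mention.end < t.end
        for t in tokens
    )


def count_partial_entities(
    sentences: Iterable[tuple[list[TokenSpan], list[EntityMention]]],
) -> int:
    """Count mentions (not tokens) that are partial at this tokenization."""
    total = 0
    for tokens, mentions in sentences:
        ordered = sorted(mentions, key=lambda m: (m.start, m.end))
        for a, b in zip(ordered[:-1], ordered[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping mentions: {a} and {b}")
        total += sum(is_partial(m, tokens) for m in ordered)
    return total


def max_sequence_length(tokenized_corpus: list[list[TokenSpan]]) -> int:
    """Maximum token count over sentences; an empty corpus is an error."""
    if not tokenized_corpus:
        raise ValueError("empty corpus")
    return max(len(sent) for sent in tokenized_corpus)


def tokenizer_report(
    documents: Iterable[Document],
    tokenizer: Callable[[str], list[TokenSpan]],
) -> TokenizerReport:
    """Run a tokenizer over title and abstract sentences of every document
    and compose the partial-entity count with the length histogram."""
    histogram: dict[int, int] = {}
    partial = 0
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
                histogram[len(tokens)] = histogram.get(len(tokens), 0) + 1
                in_sent = [
                    m for m in mentions if m.start >= s_start and m.end <= s_end
                ]
                partial += count_partial_entities([(tokens, in_sent)])
    longest = max(histogram) if histogram else 0
    return TokenizerReport(partial, longest, histogram)
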