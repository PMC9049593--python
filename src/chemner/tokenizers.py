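"""Tokenizers under comparison: WordPiece (with subword merging back to
word level) and a deterministic rule-based baseline, plus an adapter slot
for plugging in an external legacy tokenizer.

All tokenizers emit :class:`~chemner.corpora.TokenSpan` lists whose spans
are sorted, non-overlapping character ranges into the original text, so
offset-annotated mentions can be projected onto any of them.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Callable

from .corpora import TokenSpan

__all__ = [
    "WordPieceVocab",
    "wordpiece_tokenize",
    "merge_subwords",
    "rule_tokenize",
    "pretokenize",
    "ExternalTokenizerAdapter",
    "word_tokenize",
]


@dataclass(frozen=True)
class WordPieceVocab:
    """An ordered subword inventory with a continuation prefix.

    Casing is preserved throughout: a cased vocabulary is matched exactly
    and the tokenizer never lowercases.
    """

    entries: tuple[str, ...]
    continuation_prefix: str = "##"
    unknown_token: str = "[UNK]"
    _set: frozenset = field(init=False, repr=False)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("WordPiece vocabulary must be nonempty")
        if len(set(self.entries)) != len(self.entries):
            dupes = sorted({e for e in self.entries if list(self.entries).count(e) > 1})
            raise ValueError(f"duplicate vocabulary entries: {dupes[:5]}")
        if self.unknown_token not in self.entries:
            raise ValueError(f"unknown token {self.unknown_token!r} missing from vocabulary")
        object.__setattr__(self, "_set", frozenset(self.entries))

    def __contains__(self, piece: str) -> bool:
        return piece in self._set

    @classmethod
    def from_file(cls, path, **kwargs) -> "WordPieceVocab":
        """One entry per line; the line index is the subword id."""
        with open(path, encoding="utf-8") as fh:
            entries = tuple(line.rstrip("\n") for line in fh if line.rstrip("\n"))
        return cls(entries, **kwargs)

    @classmethod
    def from_words(cls, words, continuation_prefix="##", unknown_token="[UNK]") -> "WordPieceVocab":
        """Closure vocabulary over a word list: every full word plus every
        single character as both initial and continuation piece, so any word
        built from seen characters decomposes without hitting [UNK]."""
        chars = sorted({c for w in words for c in w})
        entries = [unknown_token]
        entries += sorted(set(words))
        entries += [c for c in chars if c not in set(entries)]
        entries += [continuation_prefix + c for c in chars]
        return cls(tuple(dict.fromkeys(entries)), continuation_prefix, unknown_token)


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P") or ch in "$+<=>^`|~"


def pretokenize(text: str) -> list[TokenSpan]:
    """Whitespace split, then each punctuation character becomes its own
    token — the word-level split that WordPiece refines and that merged
    subwords reconstruct."""
    spans = []
    i, n = 0, len(text)
    while i < n:
        if text[i].isspace():
            i += 1
            continue
        if _is_punct(text[i]):
            spans.append(TokenSpan(text[i], i, i + 1))
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and not _is_punct(text[j]):
            j += 1
        spans.append(TokenSpan(text[i:j], i, j))
        i = j
    return spans


def wordpiece_tokenize(text: str, vocab: WordPieceVocab) -> list[TokenSpan]:
    """Greedy longest-match-first WordPiece decomposition of each word.

    A word with no decomposition in the vocabulary closure becomes a single
    unknown token whose span still covers the whole word, so offset
    arithmetic never breaks.
    """
    out: list[TokenSpan] = []
    for word in pretokenize(text):
        pieces = _wordpiece_word(word.text, vocab)
        if pieces is None:
            out.append(TokenSpan(vocab.unknown_token, word.start, word.end))
            continue
        pos = word.start
        for k, piece in enumerate(pieces):
            raw = piece[len(vocab.continuation_prefix):] if k > 0 else piece
            out.append(TokenSpan(piece, pos, pos + len(raw)))
            pos += len(raw)
    return out


def _wordpiece_word(word: str, vocab: WordPieceVocab) -> list[str] | None:
    pieces = []
    start = 0
    n = len(word)
    while start < n:
        end = n
        found = None
        while end > start:
            piece = word[start:end]
            if start > 0:
                piece = vocab.continuation_prefix + piece
            if piece in vocab:
                found = piece
                break
            end -= 1
        if found is None:
            return None
        pieces.append(found)
        start = end
    return pieces


def merge_subwords(subwords: list[TokenSpan], continuation_prefix: str = "##"
                   ) -> tuple[list[TokenSpan], list[list[int]]]:
    """Merge maximal ``piece ##cont ##cont ...`` runs back into words.

    Returns the word-level spans plus an alignment map, word index →
    subword indices.  The merged surface is rebuilt from the prefix-stripped
    pieces and each merged span runs from the first piece's start to the
    last piece's end.
    """
    words: list[TokenSpan] = []
    alignment: list[list[int]] = []
    i = 0
    n = len(subwords)
    while i < n:
        if subwords[i].text.startswith(continuation_prefix):
            raise ValueError(
                f"continuation piece {subwords[i].text!r} at position {i} "
                "does not follow an initial piece")
        j = i + 1
        while j < n and subwords[j].text.startswith(continuation_prefix) \
                and subwords[j].start == subwords[j - 1].end:
            j += 1
        surface = subwords[i].text + "".join(
            s.text[len(continuation_prefix):] for s in subwords[i + 1 : j])
        words.append(TokenSpan(surface, subwords[i].start, subwords[j - 1].end))
        alignment.append(list(range(i, j)))
        i = j
    return words, alignment


_RULE_TOKEN = re.compile(r"[^\W_]+|[\W_]", re.UNICODE)


def rule_tokenize(text: str) -> list[TokenSpan]:
    """Deterministic rule-based tokenizer: whitespace split with every
    punctuation character detached as its own token, including hyphens
    (``GABA-benzodiazepine`` → ``GABA`` / ``-`` / ``benzodiazepine``).

    This is the in-repo stand-in for Penn-Treebank-style legacy chemical
    tokenizers; an external implementation can be plugged in through
    :class:`ExternalTokenizerAdapter` under the same span contract.
    """
    spans = []
    for m in _RULE_TOKEN.finditer(text):
        if m.group().isspace():
            continue
        spans.append(TokenSpan(m.group(), m.start(), m.end()))
    return spans


@dataclass
class ExternalTokenizerAdapter:
    """Wraps an external tokenizer callable into the TokenSpan contract.

    The callable must return ``(surface, start, end)`` triples; spans are
    checked for surface fidelity, ordering and non-overlap.
    """

    fn: Callable[[str], list[tuple[str, int, int]]]
    name: str = "external"

    def __call__(self, text: str) -> list[TokenSpan]:
        spans = [TokenSpan(s, a, b) for s, a, b in self.fn(text)]
        prev_end = -1
        for t in spans:
            if text[t.start : t.end] != t.text:
                raise ValueError(f"external tokenizer span {t} does not match source text")
            if t.start < prev_end:
                raise ValueError(f"external tokenizer spans overlap at {t}")
            prev_end = t.end
        return spans


def word_tokenize(text: str, vocab: WordPieceVocab | None = None) -> list[TokenSpan]:
    """Word-level tokenization: WordPiece then subword merging when a
    vocabulary is given, otherwise the rule tokenizer."""
    if vocab is None:
        return rule_tokenize(text)
    words, _ = merge_subwords(wordpiece_tokenize(text, vocab), vocab.continuation_prefix)
    return words
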