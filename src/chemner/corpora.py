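"""Corpus data model and readers/writers.

Covers the three dialects the toolkit touches — offset-annotated abstract
corpora in the CHEMDNER tab-separated style, token-level IOB2 corpora in a
JSON dialect, and two-column CoNLL files — plus the span/BIO conversions
that bridge character-offset annotations and token-level tags.

Offsets are 0-based, half-open, counted in Unicode code points, and are
relative to their own section (title or abstract), never to a concatenation
of the two.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

__all__ = [
    "EntityMention",
    "Document",
    "TokenSpan",
    "TaggedSequence",
    "CorpusReadError",
    "ChemdnerReadResult",
    "read_chemdner_corpus",
    "write_chemdner_corpus",
    "read_matscholar_corpus",
    "write_matscholar_corpus",
    "read_conll",
    "write_conll",
    "split_sentences",
    "spans_to_bio",
    "bio_to_spans",
    "validate_bio",
    "repair_bio",
    "entity_token_spans",
]


class CorpusReadError(ValueError):
    """Raised for malformed corpus files; the message names the line."""


@dataclass(frozen=True)
class EntityMention:
    """A gold entity as a character span into one document section."""

    section: str  # "T" (title) or "A" (abstract)
    start: int
    end: int
    surface: str
    label: str

    def __post_init__(self):
        if self.section not in ("T", "A"):
            raise ValueError(f"section must be 'T' or 'A', got {self.section!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[EntityMention] = field(default_factory=list)

    def __post_init__(self):
        if not self.doc_id:
            raise ValueError("doc_id must be nonempty")

    def section_text(self, section: str) -> str:
        return self.title if section == "T" else self.abstract

    def surface_mismatches(self) -> list[EntityMention]:
        """Mentions whose surface does not equal the sliced section text."""
        bad = []
        for m in self.mentions:
            text = self.section_text(m.section)
            if m.end > len(text) or text[m.start : m.end] != m.surface:
                bad.append(m)
        return bad


@dataclass(frozen=True)
class TokenSpan:
    """A token with its half-open character span into the source text."""

    text: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty token span [{self.start}, {self.end})")


@dataclass
class TaggedSequence:
    """One sentence: aligned token and BIO tag lists."""

    tokens: list[TokenSpan]
    tags: list[str]
    provenance: str | None = None

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.tags)} tags")

    def words(self) -> list[str]:
        return [t.text for t in self.tokens]


# ---------------------------------------------------------------------------
# BIO validation / conversion
# ---------------------------------------------------------------------------

def validate_bio(tags: list[str]) -> None:
    """Raise ValueError on the first IOB2 violation."""
    prev = "O"
    for i, tag in enumerate(tags):
        if tag == "O":
            prev = tag
            continue
        if not re.fullmatch(r"[BI]-\S+", tag):
            raise ValueError(f"malformed tag {tag!r} at position {i}")
        if tag.startswith("I-"):
            cls = tag[2:]
            if prev not in (f"B-{cls}", f"I-{cls}"):
                raise ValueError(
                    f"I-{cls} at position {i} does not continue a B-{cls}/I-{cls}")
        prev = tag


def repair_bio(tags: list[str]) -> list[str]:
    """Promote orphan I tags to B so the sequence becomes IOB2-valid."""
    out = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            cls = tag[2:]
            if prev not in (f"B-{cls}", f"I-{cls}"):
                tag = f"B-{cls}"
        out.append(tag)
        prev = tag
    return out


def spans_to_bio(
    text: str,
    tokens: list[TokenSpan],
    mentions: list[EntityMention],
) -> tuple[TaggedSequence, list[EntityMention]]:
    """Project character-span mentions onto tokens as BIO tags.

    A token is tagged as part of an entity when it overlaps the mention by
    at least one character.  Mentions with a boundary strictly inside a
    token cannot be represented exactly at this tokenization; they are
    still tagged (by the overlap rule) but returned in the second element
    as *partial* mentions.  Overlapping mentions are an error.
    """
    mentions = sorted(mentions, key=lambda m: (m.start, m.end))
    for a, b in zip(mentions[:-1], mentions[1:]):
        if b.start < a.end:
            raise ValueError(f"overlapping mentions: {a} and {b}")
    tags = ["O"] * len(tokens)
    partial: list[EntityMention] = []
    for m in mentions:
        hit = [i for i, t in enumerate(tokens) if t.start < m.end and m.start < t.end]
        if not hit:
            partial.append(m)  # mention lies entirely outside the tokens
            continue
        first = tokens[hit[0]]
        last = tokens[hit[-1]]
        boundary_inside = any(
            t.start < m.start < t.end or t.start < m.end < t.end
            for t in (first, last)
        )
        if boundary_inside:
            partial.append(m)
        tags[hit[0]] = f"B-{m.label}"
        for i in hit[1:]:
            tags[i] = f"I-{m.label}"
    validate_bio(tags)
    return TaggedSequence(tokens=list(tokens), tags=tags), partial


def bio_to_spans(seq: TaggedSequence, text: str | None = None) -> list[EntityMention]:
    """Invert :func:`spans_to_bio` for boundary-aligned mentions.

    Each maximal ``B-c (I-c)*`` run becomes one mention spanning the run's
    first token start to last token end.  When ``text`` is given the
    surface is sliced from it; otherwise token texts are joined with the
    gaps implied by the token spans (single spaces).
    """
    validate_bio(seq.tags)
    spans = entity_token_spans(seq.tags)
    out = []
    for (i, j, cls) in spans:
        start = seq.tokens[i].start
        end = seq.tokens[j - 1].end
        if text is not None:
            surface = text[start:end]
        else:
            surface = " ".join(t.text for t in seq.tokens[i:j])
        out.append(EntityMention("A", start, end, surface, cls))
    return out


def entity_token_spans(tags: list[str]) -> list[tuple[int, int, str]]:
    """Maximal B/I runs as half-open token-index spans ``(i, j, class)``."""
    spans = []
    i = 0
    n = len(tags)
    while i < n:
        if tags[i].startswith("B-"):
            cls = tags[i][2:]
            j = i + 1
            while j < n and tags[j] == f"I-{cls}":
                j += 1
            spans.append((i, j, cls))
            i = j
        else:
            i += 1
    return spans


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Half-open character ranges of sentences.

    A deliberately simple rule — split after sentence-final punctuation
    followed by whitespace — adequate for abstract-style prose; callers may
    substitute their own splitter wherever sentence ranges are consumed.
    """
    if not text:
        return []
    spans = []
    start = 0
    for m in _SENT_BOUNDARY.finditer(text):
        spans.append((start, m.start()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


# ---------------------------------------------------------------------------
# CHEMDNER dialect
# ---------------------------------------------------------------------------

@dataclass
class ChemdnerReadResult:
    """Documents plus everything that failed a fidelity check.

    ``surface_mismatches`` holds (doc_id, mention) pairs whose surface does
    not equal the sliced section text; ``orphan_annotations`` holds
    annotation rows whose document id never appears in the abstracts file.
    Neither is silently dropped: mismatched mentions stay attached to their
    document.
    """

    documents: list[Document]
    surface_mismatches: list[tuple[str, EntityMention]]
    orphan_annotations: list[tuple[str, EntityMention]]


def read_chemdner_corpus(abstracts_path, annotations_path) -> ChemdnerReadResult:
    docs: dict[str, Document] = {}
    with open(abstracts_path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusReadError(
                    f"{abstracts_path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}")
            doc_id, title, abstract = parts
            docs[doc_id] = Document(doc_id, title, abstract)
    orphans: list[tuple[str, EntityMention]] = []
    with open(annotations_path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise CorpusReadError(
                    f"{annotations_path}:{lineno}: expected 6 tab-separated fields, "
                    f"got {len(parts)}")
            doc_id, section, start, end, surface, label = parts
            try:
                mention = EntityMention(section, int(start), int(end), surface, label)
            except ValueError as exc:
                raise CorpusReadError(f"{annotations_path}:{lineno}: {exc}") from exc
            if doc_id in docs:
                docs[doc_id].mentions.append(mention)
            else:
                orphans.append((doc_id, mention))
    mismatches = [
        (doc.doc_id, m) for doc in docs.values() for m in doc.surface_mismatches()
    ]
    return ChemdnerReadResult(list(docs.values()), mismatches, orphans)


def write_chemdner_corpus(documents: list[Document], abstracts_path, annotations_path) -> None:
    with open(abstracts_path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}\n")
    with open(annotations_path, "w", encoding="utf-8") as fh:
        for doc in documents:
            for m in doc.mentions:
                fh.write(f"{doc.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.surface}\t{m.label}\n")


# ---------------------------------------------------------------------------
# Matscholar-style JSON token/tag records
# ---------------------------------------------------------------------------

def read_matscholar_corpus(path, repair: bool = False) -> list[TaggedSequence]:
    """Read token-level IOB2 sentences from a JSON list of
    ``{"tokens": [...], "tags": [...]}`` records.

    Non-chemical tag classes are preserved as-is.  Invalid IOB2 raises by
    default; with ``repair=True`` orphan I tags are promoted to B.
    """
    with open(path, encoding="utf-8") as fh:
        records = json.load(fh)
    out = []
    for i, rec in enumerate(records):
        tokens, tags = rec["tokens"], rec["tags"]
        if len(tokens) != len(tags):
            raise CorpusReadError(
                f"{path}: sentence {i}: {len(tokens)} tokens but {len(tags)} tags")
        if repair:
            tags = repair_bio(tags)
        else:
            try:
                validate_bio(tags)
            except ValueError as exc:
                raise CorpusReadError(f"{path}: sentence {i}: {exc}") from exc
        out.append(TaggedSequence(_synthetic_spans(tokens), list(tags)))
    return out


def write_matscholar_corpus(seqs: list[TaggedSequence], path) -> None:
    records = [{"tokens": s.words(), "tags": list(s.tags)} for s in seqs]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(records, fh, ensure_ascii=False, indent=0)
        fh.write("\n")


def _synthetic_spans(words: list[str]) -> list[TokenSpan]:
    """Canonical spans for token-only input: words joined by single spaces."""
    spans = []
    pos = 0
    for w in words:
        spans.append(TokenSpan(w, pos, pos + len(w)))
        pos += len(w) + 1
    return spans


# ---------------------------------------------------------------------------
# CoNLL two-column files
# ---------------------------------------------------------------------------

def read_conll(path, repair: bool = False) -> list[TaggedSequence]:
    """Two-column token/tag lines, blank line between sentences."""
    seqs: list[TaggedSequence] = []
    words: list[str] = []
    tags: list[str] = []

    def flush():
        if words:
            checked = repair_bio(tags) if repair else tags
            if not repair:
                validate_bio(checked)
            seqs.append(TaggedSequence(_synthetic_spans(words), list(checked)))
            words.clear()
            tags.clear()

    with open(path, encoding="utf-8", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                flush()
                continue
            parts = line.split(" ")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise CorpusReadError(
                    f"{path}:{lineno}: expected 'token tag', got {line!r}")
            words.append(parts[0])
            tags.append(parts[1])
    flush()
    return seqs


def write_conll(seqs: list[TaggedSequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for seq in seqs:
            for token, tag in zip(seq.tokens, seq.tags):
                fh.write(f"{token.text} {tag}\n")
            fh.write("\n")
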