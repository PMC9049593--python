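"""Seeded generator of synthetic annotated corpora.

Emulates the statistical structure of a mixed organic/inorganic chemical
NER corpus so every pipeline stage is testable without external data:
sentences mix formula-like entities (element symbols with stoichiometric
indices, e.g. ``TiO2``), organic-name-like entities built from a closed
morpheme grammar (e.g. ``methoxypropanol``), occasional two-word organic
names, distractor words, and purely numeric tokens.  A configurable
fraction of entities is deliberately fused to the following word without
whitespace (``TiO2films``) so that partial-entity counting has something
to find; the default of 5% mirrors the rough share of boundary-problem
entities seen in real offset-annotated chemical corpora.

Output is available both as offset-annotated documents (CHEMDNER-style
TSV) and as token-level gold (CoNLL / JSON), and the two views re-read to
identical tag sequences.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpora import Document, EntityMention, TaggedSequence, TokenSpan

__all__ = ["SynthConfig", "SynthCorpus", "generate_corpus", "separable_sequences", "morphology_split"]

_ELEMENTS = [
    "H", "Li", "Be", "B", "C", "N", "O", "F", "Na", "Mg", "Al", "Si", "P",
    "S", "Cl", "K", "Ca", "Ti", "V", "Cr", "Mn", "Fe", "Co", "Ni", "Cu",
    "Zn", "Ga", "Ge", "As", "Se", "Sr", "Y", "Zr", "Nb", "Mo", "Ru", "Pd",
    "Ag", "Cd", "In", "Sn", "Sb", "Te", "Ba", "La", "Ce", "Nd", "Gd", "W",
    "Pt", "Au", "Pb", "Bi",
]

_ORGANIC_PREFIXES = [
    "meth", "eth", "prop", "but", "pent", "hex", "hept", "oct", "benz",
    "phen", "tolu", "acet", "form", "glyc", "lact", "citr", "male", "succin",
]
_ORGANIC_INFIXES = ["yl", "oxy", "amino", "chloro", "fluoro", "nitro", "hydroxy", ""]
_ORGANIC_SUFFIXES = ["ane", "ene", "yne", "ol", "al", "one", "amine", "amide", "ate", "ide", "ose"]
_ORGANIC_SECOND = ["acid", "ester", "chloride", "oxide", "salt"]

_DISTRACTORS = [
    "the", "a", "an", "of", "in", "on", "at", "with", "for", "from", "into",
    "was", "were", "is", "are", "been", "being", "has", "have", "had",
    "grown", "measured", "observed", "synthesized", "prepared", "annealed",
    "deposited", "characterized", "obtained", "reported", "studied",
    "films", "samples", "crystals", "layers", "substrates", "powders",
    "temperature", "pressure", "spectra", "structure", "phase", "method",
    "results", "analysis", "properties", "surface", "solution", "reaction",
    "using", "during", "after", "before", "under", "between", "via",
    "show", "shows", "showed", "exhibit", "exhibits", "increase", "decrease",
    "high", "low", "large", "small", "thin", "thick", "pure", "mixed",
    "we", "this", "these", "that", "both", "each", "other", "further",
    "K", "mol", "nm", "eV", "GPa", "mbar", "hours", "minutes", "degrees",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    ``entity_rate`` is the per-token probability of starting a chemical
    entity, ``numeric_rate`` the per-token probability of a purely numeric
    token, ``organic_fraction`` the share of entities drawn from the
    organic-name grammar (the rest are inorganic formulas), and
    ``fused_fraction`` the share of entities glued to the following word
    without whitespace.
    """

    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (3, 6)
    tokens_per_sentence: tuple[int, int] = (6, 14)
    organic_fraction: float = 0.5
    entity_rate: float = 0.15
    numeric_rate: float = 0.05
    fused_fraction: float = 0.05
    two_word_fraction: float = 0.15
    label: str = "CHEM"
    extra_classes: tuple[str, ...] = ()
    extra_class_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("organic_fraction", "entity_rate", "numeric_rate",
                     "fused_fraction", "two_word_fraction", "extra_class_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SynthCorpus:
    documents: list[Document]
    sequences: list[TaggedSequence]  # token-level gold, one per sentence
    config: SynthConfig = field(repr=False, default=None)

    @property
    def n_mentions(self) -> int:
        return sum(len(d.mentions) for d in self.documents)


def _formula(rng: random.Random) -> str:
    parts = []
    for _ in range(rng.randint(1, 3)):
        parts.append(rng.choice(_ELEMENTS))
        if rng.random() < 0.6:
            parts.append(str(rng.randint(2, 9)))
    return "".join(parts)


def _organic_word(rng: random.Random) -> str:
    word = rng.choice(_ORGANIC_PREFIXES)
    for _ in range(rng.randint(0, 2)):
        word += rng.choice(_ORGANIC_INFIXES)
    return word + rng.choice(_ORGANIC_SUFFIXES)


def _entity(rng: random.Random, cfg: SynthConfig) -> list[str]:
    if rng.random() < cfg.organic_fraction:
        words = [_organic_word(rng)]
        if rng.random() < cfg.two_word_fraction:
            words.append(rng.choice(_ORGANIC_SECOND))
        return words
    return [_formula(rng)]


def _numeric(rng: random.Random) -> str:
    if rng.random() < 0.3:
        return f"{rng.randint(0, 99)}.{rng.randint(0, 99)}"
    return str(rng.randint(0, 5000))


def generate_corpus(config: SynthConfig | None = None, **overrides) -> SynthCorpus:
    """Generate a seeded synthetic corpus; same config ⇒ identical output.

    Token-level gold tags follow the overlap policy for fused entities:
    the fused token is tagged as (the beginning of) the entity even though
    the character-offset mention covers only the entity's own characters,
    so the mention is partial at this tokenization.
    """
    if config is None:
        config = SynthConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    rng = random.Random(config.seed)
    documents: list[Document] = []
    sequences: list[TaggedSequence] = []
    for d in range(config.n_docs):
        doc_id = f"synth{d:05d}"
        n_sent = rng.randint(*config.sentences_per_doc)
        sent_seqs = [_sentence(rng, config) for _ in range(n_sent)]
        # first sentence is the title, the rest the abstract
        title_tokens, title_tags, title_mentions, title_text = sent_seqs[0]
        abstract_parts = []
        abs_mentions: list[EntityMention] = []
        offset = 0
        for tokens, tags, ments, text in sent_seqs[1:]:
            for (mstart, mend, surface, label) in ments:
                abs_mentions.append(
                    EntityMention("A", mstart + offset, mend + offset, surface, label))
            shifted = [TokenSpan(t.text, t.start + offset, t.end + offset) for t in tokens]
            sequences.append(TaggedSequence(shifted, list(tags), provenance=doc_id))
            abstract_parts.append(text)
            offset += len(text) + 1
        abstract = " ".join(abstract_parts)
        mentions = [
            EntityMention("T", ms, me, surf, lab) for (ms, me, surf, lab) in title_mentions
        ] + abs_mentions
        documents.append(Document(doc_id, title_text, abstract, mentions))
        sequences.insert(
            len(sequences) - (n_sent - 1),
            TaggedSequence(list(title_tokens), list(title_tags), provenance=doc_id),
        )
    return SynthCorpus(documents, sequences, config)


def _sentence(rng: random.Random, cfg: SynthConfig):
    """One sentence: returns (tokens, tags, mentions, text).

    Mentions are (start, end, surface, label) in sentence-local offsets.
    """
    n_tokens = rng.randint(*cfg.tokens_per_sentence)
    tokens: list[TokenSpan] = []
    tags: list[str] = []
    mentions: list[tuple[int, int, str, str]] = []
    parts: list[str] = []
    pos = 0

    def emit(text: str, tag: str):
        nonlocal pos
        tokens.append(TokenSpan(text, pos, pos + len(text)))
        tags.append(tag)
        parts.append(text)
        pos += len(text) + 1

    i = 0
    while i < n_tokens:
        r = rng.random()
        if r < cfg.entity_rate:
            words = _entity(rng, cfg)
            fused = rng.random() < cfg.fused_fraction
            if fused and len(words) == 1:
                tail = rng.choice(_DISTRACTORS)
                surface = words[0]
                emit(surface + tail, f"B-{cfg.label}")
                mentions.append((pos - len(surface + tail) - 1,
                                 pos - len(tail) - 1, surface, cfg.label))
                i += 1
            else:
                start = pos
                for k, w in enumerate(words):
                    emit(w, f"B-{cfg.label}" if k == 0 else f"I-{cfg.label}")
                surface = " ".join(words)
                mentions.append((start, start + len(surface), surface, cfg.label))
                i += len(words)
        elif r < cfg.entity_rate + cfg.numeric_rate:
            emit(_numeric(rng), "O")
            i += 1
        elif cfg.extra_classes and r < cfg.entity_rate + cfg.numeric_rate + cfg.extra_class_rate:
            cls = rng.choice(cfg.extra_classes)
            emit(rng.choice(_DISTRACTORS), f"B-{cls}")
            i += 1
        else:
            emit(rng.choice(_DISTRACTORS), "O")
            i += 1
    text = " ".join(parts) + " ."
    tokens.append(TokenSpan(".", pos, pos + 1))
    tags.append("O")
    return tokens, tags, mentions, text


def separable_sequences(
    n_sentences: int,
    seed: int,
    entity_rate: float = 0.2,
    label: str = "CHEM",
) -> list[TaggedSequence]:
    """A linearly separable token corpus: entity surfaces come from a
    closed vocabulary disjoint from the distractor vocabulary, so a tagger
    that memorizes surface forms can reach near-perfect entity F1."""
    rng = random.Random(seed)
    entity_vocab = sorted({_formula(rng) for _ in range(120)} | {_organic_word(rng) for _ in range(120)})
    out = []
    for _ in range(n_sentences):
        n = rng.randint(5, 12)
        words, tags = [], []
        for _ in range(n):
            if rng.random() < entity_rate:
                words.append(rng.choice(entity_vocab))
                tags.append(f"B-{label}")
            else:
                words.append(rng.choice(_DISTRACTORS))
                tags.append("O")
        spans = []
        pos = 0
        for w in words:
            spans.append(TokenSpan(w, pos, pos + len(w)))
            pos += len(w) + 1
        out.append(TaggedSequence(spans, tags))
    return out


def morphology_split(
    n_sentences: int,
    seed: int,
    holdout_stems: float = 0.5,
    label: str = "CHEM",
) -> tuple[list[TaggedSequence], list[TaggedSequence]]:
    """Train/dev corpora with heavy surface-form overlap between entities
    and distractors: both are stem+suffix words over a shared stem list,
    only the suffix decides entityhood, and dev sentences use held-out
    stems.  A tagger with access to character shape can generalize; one
    keyed to whole-word identity sees only unknown words in dev."""
    rng = random.Random(seed)
    stems = sorted({_organic_word(rng)[:-3] or "meth" for _ in range(200)})
    rng.shuffle(stems)
    cut = max(1, int(len(stems) * (1 - holdout_stems)))
    train_stems, dev_stems = stems[:cut], stems[cut:]
    chem_suffixes = ["ol", "ene", "amine", "ate"]
    plain_suffixes = ["ly", "ing", "ness", "tion"]

    def build(n, pool):
        seqs = []
        for _ in range(n):
            L = rng.randint(5, 10)
            words, tags = [], []
            for _ in range(L):
                r = rng.random()
                if r < 0.2:
                    words.append(rng.choice(pool) + rng.choice(chem_suffixes))
                    tags.append(f"B-{label}")
                elif r < 0.4:
                    words.append(rng.choice(pool) + rng.choice(plain_suffixes))
                    tags.append("O")
                else:
                    words.append(rng.choice(_DISTRACTORS))
                    tags.append("O")
            spans = []
            pos = 0
            for w in words:
                spans.append(TokenSpan(w, pos, pos + len(w)))
                pos += len(w) + 1
            seqs.append(TaggedSequence(spans, tags))
        return seqs

    n_dev = max(1, n_sentences // 5)
    return build(n_sentences, train_stems), build(n_dev, dev_stems)
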