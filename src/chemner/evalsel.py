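"""Entity-level scoring and precision-first model selection.

Scoring is strict: a predicted entity counts as a true positive only when
both token boundaries and the class match a gold entity exactly.  Model
selection reflects an information-extraction stance — precision errors
poison every downstream step, while recall above a floor buys little — so
among candidates whose development recall exceeds the floor (85% by
default, strict inequality) the one with the highest precision wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpora import TaggedSequence, entity_token_spans

__all__ = ["PRF", "entity_prf", "prf_from_sequences", "select_model", "Candidate"]


@dataclass(frozen=True)
class PRF:
    precision: float  # percent
    recall: float  # percent
    f1: float  # percent
    tp: int
    n_gold: int
    n_pred: int


def entity_prf(gold: Sequence[Iterable], pred: Sequence[Iterable]) -> PRF:
    """Micro-averaged strict P/R/F1 in percent.

    ``gold`` and ``pred`` are parallel per-sentence collections of hashable
    entity spans (e.g. ``(start, end, class)`` tuples).  With no predicted
    and no gold entities precision and recall are defined as 100; with
    predictions but no matches they are 0.
    """
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold sentences vs {len(pred)} predicted")
    tp = n_gold = n_pred = 0
    for g, p in zip(gold, pred):
        gs, ps = set(g), set(p)
        tp += len(gs & ps)
        n_gold += len(gs)
        n_pred += len(ps)
    precision = 100.0 * tp / n_pred if n_pred else (100.0 if n_gold == 0 else 0.0)
    recall = 100.0 * tp / n_gold if n_gold else (100.0 if n_pred == 0 else 0.0)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return PRF(precision, recall, f1, tp, n_gold, n_pred)


def prf_from_sequences(
    gold_seqs: Sequence[TaggedSequence], pred_seqs: Sequence[TaggedSequence]
) -> PRF:
    """Strict entity scoring of predicted against gold tag sequences."""
    gold = [entity_token_spans(s.tags) for s in gold_seqs]
    pred = [entity_token_spans(s.tags) for s in pred_seqs]
    return entity_prf(gold, pred)


@dataclass(frozen=True)
class Candidate:
    config: object
    precision: float
    recall: float


def select_model(
    candidates: Sequence[Candidate | tuple], recall_floor: float = 85.0
):
    """Return the config of the highest-precision candidate whose recall is
    strictly above the floor; ties go to higher recall, then first listed.

    Raises when no candidate clears the floor, reporting the best recall
    actually achieved.
    """
    if not candidates:
        raise ValueError("no candidates")
    cands = [c if isinstance(c, Candidate) else Candidate(*c) for c in candidates]
    eligible = [c for c in cands if c.recall > recall_floor]
    if not eligible:
        best = max(c.recall for c in cands)
        raise ValueError(
            f"no candidate exceeds the recall floor of {recall_floor}; "
            f"best achievable recall is {best}")
    winner = eligible[0]
    for c in eligible[1:]:
        if (c.precision, c.recall) > (winner.precision, winner.recall):
            winner = c
    return winner.config
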