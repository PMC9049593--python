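"""Sliding-window inference for sequences longer than an encoder's limit.

Encoders pretrained on sequences of at most *n* tokens cannot score longer
sentences directly.  The sequence is therefore covered by overlapping
windows of length *n* (*n* divisible by 4) at stride *n*/2, and only the
centrally-placed predictions of each window are kept: the first window
keeps its first 3*n*/4 labels, intermediate windows their middle *n*/2,
and the final window — anchored at ``L - n`` so it is always full length —
discards at least its first *n*/4 labels.  The kept ranges partition the
sequence exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

from .corpora import TaggedSequence, repair_bio

__all__ = ["Window", "WindowPlan", "plan_windows", "predict_long_sequence", "DEFAULT_WINDOW"]

#: Default window length, matching the usual pretraining limit of deep
#: bidirectional encoders.
DEFAULT_WINDOW = 512


@dataclass(frozen=True)
class Window:
    win_start: int
    win_end: int
    keep_start: int
    keep_end: int


@dataclass(frozen=True)
class WindowPlan:
    n: int
    length: int
    windows: tuple[Window, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "length": self.length,
                "windows": [
                    [w.win_start, w.win_end, w.keep_start, w.keep_end]
                    for w in self.windows
                ],
            }
        )


def plan_windows(L: int, n: int) -> WindowPlan:
    """Plan windows and keep-ranges covering a sequence of length ``L``.

    When the stride ``n/2`` does not divide ``L`` the final window overlaps
    its predecessor by more than ``n/2``; its keep-start is then clamped to
    the previous keep-end, preserving the partition while still discarding
    at least the first ``n/4`` labels of the final window.
    """
    if L < 1:
        raise ValueError(f"sequence length must be >= 1, got {L}")
    if n < 4 or n % 4 != 0:
        raise ValueError(f"window length must be a positive multiple of 4, got {n}")
    if L <= n:
        return WindowPlan(n, L, (Window(0, L, 0, L),))
    q = n // 4
    stride = n // 2
    windows = [Window(0, n, 0, 3 * q)]
    start = stride
    while start < L - n:
        windows.append(Window(start, start + n, start + q, start + 3 * q))
        start += stride
    prev_keep_end = windows[-1].keep_end
    final_start = L - n
    keep_start = max(final_start + q, prev_keep_end)
    windows.append(Window(final_start, L, keep_start, L))
    _check_partition(windows, L)
    return WindowPlan(n, L, tuple(windows))


def _check_partition(windows: list[Window], L: int) -> None:
    pos = 0
    for w in windows:
        if not (w.win_start <= w.keep_start <= w.keep_end <= w.win_end):
            raise AssertionError(f"keep range escapes its window: {w}")
        if w.keep_start != pos:
            raise AssertionError(f"keep ranges do not tile [0, {L}): gap at {pos}")
        pos = w.keep_end
    if pos != L:
        raise AssertionError(f"keep ranges end at {pos}, expected {L}")


def predict_long_sequence(
    predict: Callable[[Sequence[str]], list[str]],
    words: Sequence[str],
    n: int = DEFAULT_WINDOW,
) -> list[str]:
    """Tag an arbitrarily long sequence with a length-limited tagger.

    ``predict`` maps a word list (length ≤ n) to a BIO tag list.  For
    ``L ≤ n`` the output is identical to calling ``predict`` directly.
    Otherwise each planned window is tagged, only tags inside its keep
    range are retained, and the concatenation is repaired to BIO validity
    at the seams (an orphan I after a keep boundary is promoted to B, since
    entities may straddle seams).
    """
    words = list(words)
    if not words:
        return []
    plan = plan_windows(len(words), n)
    if len(plan.windows) == 1:
        return list(predict(words))
    merged: list[str] = []
    for w in plan.windows:
        tags = list(predict(words[w.win_start : w.win_end]))
        if len(tags) != w.win_end - w.win_start:
            raise ValueError(
                f"tagger returned {len(tags)} tags for a window of "
                f"{w.win_end - w.win_start} words")
        merged.extend(tags[w.keep_start - w.win_start : w.keep_end - w.win_start])
    return repair_bio(merged)


def predict_long_tagged(
    predict: Callable[[Sequence[str]], list[str]],
    seq_words: Sequence[str],
    n: int = DEFAULT_WINDOW,
) -> TaggedSequence:
    from .corpora import _synthetic_spans

    tags = predict_long_sequence(predict, seq_words, n)
    return TaggedSequence(_synthetic_spans(list(seq_words)), tags)
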