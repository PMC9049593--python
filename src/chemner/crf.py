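"""Linear-chain conditional random field with a BIO transition mask.

The CRF scores whole tag sequences (emission + transition + boundary
scores) and is constrained so that probability mass is placed only on
BIO-valid sequences: a sequence may not start with I, O may not be
followed by I, and I must continue the class of the preceding B/I tag.
Masked transitions receive a large negative penalty during normalization
(so the partition function over invalid sequences underflows to zero)
and hard ``-inf`` during Viterbi decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools

import numpy as np

from .autodiff import Tensor, logsumexp
from .nn import Module, Parameter

__all__ = ["TagScheme", "CRF", "MASK_PENALTY"]

#: Finite stand-in for -inf inside the differentiable forward recursion;
#: exp(-1e4) underflows to exactly 0.0 in float64, so the partition function
#: matches a valid-sequences-only enumeration to machine precision.
MASK_PENALTY = -1.0e4


@dataclass(frozen=True)
class TagScheme:
    """Ordered BIO tag inventory with its transition constraints.

    ``O`` is always tag index 0, followed by ``B-c``/``I-c`` pairs per class;
    the Viterbi tie-break toward the lowest index therefore prefers ``O``.
    """

    classes: tuple[str, ...]
    tags: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        tags = ["O"]
        for c in self.classes:
            tags += [f"B-{c}", f"I-{c}"]
        object.__setattr__(self, "tags", tuple(tags))

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def index(self, tag: str) -> int:
        return self.tags.index(tag)

    def encode(self, tags: list[str]) -> np.ndarray:
        return np.array([self.tags.index(t) for t in tags], dtype=np.intp)

    def decode(self, ids) -> list[str]:
        return [self.tags[int(i)] for i in ids]

    def allowed_start(self) -> np.ndarray:
        """Boolean vector: which tags may begin a sequence (no initial I)."""
        return np.array([not t.startswith("I-") for t in self.tags])

    def allowed_transitions(self) -> np.ndarray:
        """Boolean (from, to) matrix of BIO-valid transitions."""
        K = self.n_tags
        ok = np.ones((K, K), dtype=bool)
        for j, to in enumerate(self.tags):
            if not to.startswith("I-"):
                continue
            cls = to[2:]
            for i, frm in enumerate(self.tags):
                ok[i, j] = frm in (f"B-{cls}", f"I-{cls}")
        return ok

    def is_valid(self, tags: list[str]) -> bool:
        if any(t not in self.tags for t in tags):
            return False
        ids = self.encode(tags)
        if len(ids) == 0:
            return True
        if not self.allowed_start()[ids[0]]:
            return False
        ok = self.allowed_transitions()
        return all(ok[a, b] for a, b in zip(ids[:-1], ids[1:]))


class CRF(Module):
    def __init__(self, scheme: TagScheme, rng: np.random.Generator):
        K = scheme.n_tags
        self.scheme = scheme
        self.transitions = Parameter(rng.normal(0, 0.01, size=(K, K)))
        self.start = Parameter(rng.normal(0, 0.01, size=K))
        self.end = Parameter(rng.normal(0, 0.01, size=K))
        self._trans_pen = np.where(scheme.allowed_transitions(), 0.0, MASK_PENALTY)
        self._start_pen = np.where(scheme.allowed_start(), 0.0, MASK_PENALTY)

    # -- training objective ---------------------------------------------------
    def log_likelihood(self, emissions: Tensor, tags: np.ndarray, mask: np.ndarray) -> Tensor:
        """Sum over the batch of ``log p(tags | emissions)``.

        emissions: Tensor (B, T, K); tags: int (B, T); mask: float (B, T).
        Gold tags must be valid under the scheme (checked).
        """
        self._check_gold(tags, mask)
        return self._score(emissions, tags, mask) - self.partition(emissions, mask)

    def _check_gold(self, tags: np.ndarray, mask: np.ndarray):
        ok_t = self.scheme.allowed_transitions()
        ok_s = self.scheme.allowed_start()
        for b in range(tags.shape[0]):
            L = int(mask[b].sum())
            seq = tags[b, :L]
            if L and not ok_s[seq[0]]:
                raise ValueError(f"gold sequence {b} starts with forbidden tag "
                                 f"{self.scheme.tags[seq[0]]}")
            for a, c in zip(seq[:-1], seq[1:]):
                if not ok_t[a, c]:
                    raise ValueError(
                        f"gold sequence {b} contains forbidden transition "
                        f"{self.scheme.tags[a]} -> {self.scheme.tags[c]}")

    def _score(self, emissions: Tensor, tags: np.ndarray, mask: np.ndarray) -> Tensor:
        B, T, K = emissions.shape
        rows = np.arange(B)
        lengths = mask.sum(axis=1).astype(int)
        score = (self.start + Tensor(self._start_pen))[tags[:, 0]]
        score = score + emissions[rows, 0, tags[:, 0]]
        trans = self.transitions + Tensor(self._trans_pen)
        for t in range(1, T):
            step = trans[tags[:, t - 1], tags[:, t]] + emissions[rows, t, tags[:, t]]
            score = score + Tensor(mask[:, t]) * step
        score = score + self.end[tags[rows, lengths - 1]]
        return score.sum()

    def partition(self, emissions: Tensor, mask: np.ndarray) -> Tensor:
        """Sum over the batch of log Z via the forward recursion."""
        B, T, K = emissions.shape
        trans = (self.transitions + Tensor(self._trans_pen)).reshape(1, K, K)
        alpha = self.start + Tensor(self._start_pen) + emissions[:, 0, :]
        for t in range(1, T):
            nxt = logsumexp(alpha.reshape(B, K, 1) + trans, axis=1) + emissions[:, t, :]
            m = Tensor(mask[:, t][:, None])
            alpha = m * nxt + Tensor(1.0 - mask[:, t][:, None]) * alpha
        return logsumexp(alpha + self.end, axis=1).sum()

    # -- decoding -------------------------------------------------------------
    def viterbi(self, emissions: np.ndarray) -> list[int]:
        """Best mask-valid tag sequence for one sentence (T, K).

        Ties are broken toward the lowest tag index (argmax returns the
        first maximum), so an all-zero score matrix decodes to all-O.
        """
        emissions = np.asarray(emissions, dtype=np.float64)
        T, K = emissions.shape
        if T == 0:
            return []
        trans = self.transitions.data + np.where(self.scheme.allowed_transitions(), 0.0, -np.inf)
        delta = self.start.data + np.where(self.scheme.allowed_start(), 0.0, -np.inf) + emissions[0]
        back = np.zeros((T, K), dtype=np.intp)
        for t in range(1, T):
            cand = delta[:, None] + trans  # (from, to)
            back[t] = np.argmax(cand, axis=0)
            delta = cand[back[t], np.arange(K)] + emissions[t]
        delta = delta + self.end.data
        best = int(np.argmax(delta))
        path = [best]
        for t in range(T - 1, 0, -1):
            best = int(back[t, best])
            path.append(best)
        return path[::-1]
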