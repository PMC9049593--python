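"""Neural building blocks for the sequence taggers.

Layers are written against :mod:`chemner.autodiff` and operate on batches of
padded sequences with explicit masks, which keeps CPU training of the
BiLSTM-CRF taggers fast enough for desk-scale corpora.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, stack

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "LSTM",
    "BiLSTM",
    "CharCNN",
    "Adam",
]


class Parameter(Tensor):
    def __init__(self, data, requires_grad: bool = True):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=requires_grad)


class Module:
    """Container with recursive parameter discovery and a freeze switch."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def trainable_parameters(self) -> list[Parameter]:
        return [p for p in self.parameters() if p.requires_grad]

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.requires_grad = False
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


def _collect(value):
    if isinstance(value, Parameter):
        yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Parameter(_glorot(rng, n_in, n_out))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator, scale: float = 0.1):
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_vocab, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return self.weight[np.asarray(ids, dtype=np.intp)]


class LSTM(Module):
    """Single-direction LSTM over a padded batch.

    Input ``(T, B, D)``, mask ``(T, B)`` with 1 on real tokens; the hidden
    state is frozen through masked (padding) steps, so running the reversed
    sequence of an end-padded batch yields correct backward-direction states.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        self.w = Parameter(_glorot(rng, n_in + n_hidden, 4 * n_hidden))
        self.b = Parameter(np.zeros(4 * n_hidden))
        # forget-gate bias at 1 helps gradient flow early in training
        self.b.data[n_hidden : 2 * n_hidden] = 1.0

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        T, B, _ = x.shape
        H = self.n_hidden
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        outputs = []
        for t in range(T):
            xt = x[t]
            zc = concatenate([xt, h], axis=1) @ self.w + self.b
            i = zc[:, 0:H].sigmoid()
            f = zc[:, H : 2 * H].sigmoid()
            g = zc[:, 2 * H : 3 * H].tanh()
            o = zc[:, 3 * H : 4 * H].sigmoid()
            c_new = f * c + i * g
            h_new = o * c_new.tanh()
            m = Tensor(mask[t][:, None])
            keep = Tensor(1.0 - mask[t][:, None])
            c = m * c_new + keep * c
            h = m * h_new + keep * h
            outputs.append(h)
        return stack(outputs, axis=0)


class BiLSTM(Module):
    """Stack of bidirectional LSTM layers; concatenates both directions."""

    def __init__(self, n_in: int, n_hidden: int, n_layers: int, rng: np.random.Generator):
        self.layers = []
        dim = n_in
        for _ in range(n_layers):
            fwd = LSTM(dim, n_hidden, rng)
            bwd = LSTM(dim, n_hidden, rng)
            self.layers.append((fwd, bwd))
            dim = 2 * n_hidden
        self.n_out = dim

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        lengths = mask.sum(axis=0).astype(int)  # (B,)
        for fwd, bwd in self.layers:
            out_f = fwd(x, mask)
            x_rev, mask_rev = _reverse_padded(x, mask, lengths)
            out_b = bwd(x_rev, mask_rev)
            out_b, _ = _reverse_padded(out_b, mask_rev, lengths)
            x = concatenate([out_f, out_b], axis=2)
        return x


def _reverse_padded(x: Tensor, mask: np.ndarray, lengths: np.ndarray):
    """Reverse each sequence within its true length (padding stays at the end)."""
    T, B = mask.shape
    idx = np.zeros((T, B), dtype=np.intp)
    base = np.arange(T)
    for b in range(B):
        L = lengths[b]
        idx[:L, b] = L - 1 - base[:L]
        idx[L:, b] = base[L:]
    cols = np.broadcast_to(np.arange(B), (T, B))
    return x[idx, cols], mask[idx, cols]


class CharCNN(Module):
    """Character convolution producing a fixed-size vector per word.

    Words arrive as a padded ``(N, L)`` array of character ids (0 = pad);
    each kernel width convolves the character embeddings, applies ReLU and
    max-pools over positions, and the pooled features are concatenated.
    """

    def __init__(
        self,
        n_chars: int,
        char_dim: int,
        n_filters: int,
        kernel_widths: tuple[int, ...],
        rng: np.random.Generator,
    ):
        self.emb = Embedding(n_chars, char_dim, rng)
        self.kernel_widths = tuple(kernel_widths)
        self.filters = [
            Linear(w * char_dim, n_filters, rng) for w in self.kernel_widths
        ]
        self.n_out = n_filters * len(self.kernel_widths)

    def __call__(self, char_ids: np.ndarray) -> Tensor:
        char_ids = np.asarray(char_ids, dtype=np.intp)
        N, L = char_ids.shape
        need = max(self.kernel_widths)
        if L < need:  # pad so every kernel has at least one window
            char_ids = np.pad(char_ids, ((0, 0), (0, need - L)))
            L = need
        e = self.emb(char_ids)  # (N, L, D)
        feats = []
        for w, lin in zip(self.kernel_widths, self.filters):
            windows = concatenate([e[:, i : L - w + 1 + i, :] for i in range(w)], axis=2)
            conv = lin(windows).relu()  # (N, L-w+1, F)
            feats.append(conv.max(axis=1))
        return concatenate(feats, axis=1)  # (N, n_out)


class Adam:
    """Adam optimizer with the standard bias correction."""

    def __init__(self, params: list[Parameter], lr: float = 1e-2, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
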