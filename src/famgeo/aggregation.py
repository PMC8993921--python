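"""Sequence-length-invariant pooling of per-residue representations.

A sequence model emits local representations r_1..r_L (one D-vector per
residue); downstream predictors need a fixed-size global vector.  The
operators here cover the standard menu: uniform averaging, learned
attention weighting (single-head dot-product with a query vector), light
attention (per-dimension convolutional weights), elementwise maximum,
mean+max concatenation, top-K attention averaging, lossless concatenation
with padding (G = max_len * local_dim, default 512 * 4 = 2048), and a
learned bottleneck autoencoder that compresses the whole padded sequence
into a fixed-size code.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from famgeo._nn import MLP, Adam, softmax, log_softmax


@dataclass
class LocalReps:
    """Per-position representation matrix (L, D) with a validity mask."""

    matrix: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if self.mask is None:
            self.mask = np.ones(self.matrix.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape[0] != self.matrix.shape[0]:
            raise ValueError("mask length must equal L")
        if self.matrix.shape[0] < 1:
            raise ValueError("need at least one position")


@dataclass
class GlobalRep:
    vector: np.ndarray
    strategy: str
    params: dict = field(default_factory=dict)

    @property
    def G(self) -> int:
        return self.vector.shape[0]


def _attention_weights(reps: np.ndarray, mask: np.ndarray, query: np.ndarray) -> np.ndarray:
    scores = reps @ np.asarray(query, dtype=float)
    scores = np.where(mask, scores, -np.inf)
    return softmax(scores)


def pool(reps: LocalReps, strategy: str, params: dict | None = None) -> GlobalRep:
    """Aggregate local representations into a fixed-size global vector.

    Strategies: 'mean' (uniform average), 'attention' (softmax over
    dot-product scores with params['query']), 'light_attention'
    (per-dimension depthwise-convolution scores, params['kernel'] of shape
    (k, D), softmax over positions per dimension), 'max' (elementwise
    maximum), 'meanmax' (concatenated mean and max halves), 'kmax' (mean of
    the K highest-attention positions, default K=5; K > L falls back to all
    positions).
    """
    params = dict(params or {})
    X, mask = reps.matrix, reps.mask
    if not mask.any():
        raise ValueError("empty mask: no valid positions to pool")
    valid = X[mask]
    D = X.shape[1]
    if strategy == "mean":
        vec = valid.mean(axis=0)
    elif strategy == "max":
        vec = valid.max(axis=0)
    elif strategy == "meanmax":
        vec = np.concatenate([valid.mean(axis=0), valid.max(axis=0)])
    elif strategy == "attention":
        q = params.get("query")
        if q is None:
            raise ValueError("attention pooling requires params['query']")
        w = _attention_weights(X, mask, q)
        vec = w @ X
    elif strategy == "light_attention":
        kernel = np.atleast_2d(np.asarray(params.get("kernel", np.ones((1, D)))))
        if kernel.shape[1] != D:
            raise ValueError("light-attention kernel must have D columns")
        k = kernel.shape[0]
        pad = k // 2
        Xp = np.pad(X, ((pad, k - 1 - pad), (0, 0)))
        scores = np.stack(
            [np.sum(Xp[i : i + k] * kernel, axis=0) for i in range(X.shape[0])]
        )  # (L, D) depthwise conv
        scores = np.where(mask[:, None], scores, -np.inf)
        w = softmax(scores, axis=0)
        vec = np.sum(w * X, axis=0)
    elif strategy == "kmax":
        K = int(params.get("k", 5))
        q = params.get("query")
        w = _attention_weights(X, mask, q) if q is not None else np.where(mask, 1.0, -np.inf)
        n_valid = int(mask.sum())
        if K >= n_valid:
            vec = valid.mean(axis=0)
        else:
            top = np.argsort(-w, kind="stable")[:K]
            vec = X[top].mean(axis=0)
    else:
        raise ValueError(f"unknown pooling strategy {strategy!r}")
    return GlobalRep(vec, strategy, params)


def concat_pool(
    reps: LocalReps,
    max_len: int = 512,
    local_dim: int = 4,
    pad_value: float = 0.0,
) -> GlobalRep:
    """Lossless aggregation: concatenate the local rows in order and pad to a
    fixed budget, G = max_len * local_dim (2048 with the defaults)."""
    X = reps.matrix
    L, D = X.shape
    if D != local_dim:
        raise ValueError(f"local dimension {D} != configured {local_dim}")
    if L > max_len:
        raise ValueError(f"sequence length {L} exceeds max_len={max_len}")
    vec = np.full(max_len * local_dim, float(pad_value))
    vec[: L * D] = X.ravel()
    return GlobalRep(vec, "concat", {"max_len": max_len, "local_dim": local_dim, "L": L})


def concat_unpool(rep: GlobalRep) -> np.ndarray:
    """Inverse of concat_pool: recover the exact local rows."""
    L = rep.params["L"]
    D = rep.params["local_dim"]
    return rep.vector[: L * D].reshape(L, D)


# ---------------------------------------------------------------- bottleneck


@dataclass
class BottleneckModel:
    """Learned aggregation: autoencoder forcing the padded one-hot sequence
    through a fixed-size code."""

    encoder: MLP
    decoder: MLP
    max_len: int
    n_classes: int
    code_dim: int
    seed: int

    def encode_flat(self, x_flat: np.ndarray) -> np.ndarray:
        code, _ = self.encoder.forward(np.atleast_2d(x_flat))
        return code


def _pad_corpus(seqs, max_len: int, n_classes: int, pad_class: int) -> np.ndarray:
    out = np.full((len(seqs), max_len), pad_class, dtype=np.int64)
    for i, s in enumerate(seqs):
        s = np.asarray(s, dtype=np.int64)
        if s.shape[0] > max_len:
            raise ValueError(f"sequence of length {s.shape[0]} exceeds max_len={max_len}")
        out[i, : s.shape[0]] = s
    return out


def fit_bottleneck(
    corpus,
    max_len: int = 128,
    n_classes: int = 21,
    code_dim: int = 32,
    hidden: int = 64,
    epochs: int = 150,
    lr: float = 2e-3,
    pad_class: int | None = None,
    seed: int = 0,
) -> BottleneckModel:
    """Train the bottleneck aggregator by reconstruction cross-entropy.

    `corpus` is a list of integer-coded sequences (length <= max_len); they
    are padded with the gap/pad class to a common length.  The encoder maps
    the padded one-hot sequence to a `code_dim` global code, the decoder maps
    the code back to per-position logits.  Same seed gives identical models.
    """
    pad_class = n_classes - 1 if pad_class is None else pad_class
    codes = _pad_corpus(corpus, max_len, n_classes, pad_class)
    N = codes.shape[0]
    x = np.eye(n_classes)[codes].reshape(N, -1)
    rng = np.random.default_rng(seed)
    enc = MLP([max_len * n_classes, hidden, code_dim], rng)
    dec = MLP([code_dim, hidden, max_len * n_classes], rng)
    opt = Adam(enc.params + dec.params, lr=lr)
    idx_n = np.arange(N)[:, None]
    idx_l = np.arange(max_len)[None, :]
    for epoch in range(epochs):
        code, enc_acts = enc.forward(x)
        logits, dec_acts = dec.forward(code)
        logp = log_softmax(logits.reshape(N, max_len, n_classes))
        loss = float(-logp[idx_n, idx_l, codes].mean())
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        g = np.exp(logp)
        g[idx_n, idx_l, codes] -= 1.0
        g /= N * max_len
        dec_grads, g_code = dec.backward(dec_acts, g.reshape(N, -1))
        enc_grads, _ = enc.backward(enc_acts, g_code)
        opt.step(enc_grads + dec_grads)
    return BottleneckModel(enc, dec, max_len, n_classes, code_dim, seed)


def bottleneck_encode(model: BottleneckModel, sequence) -> GlobalRep:
    """Fixed-size global code for one integer-coded sequence."""
    codes = _pad_corpus([sequence], model.max_len, model.n_classes, model.n_classes - 1)
    x = np.eye(model.n_classes)[codes[0]].ravel()
    code = model.encode_flat(x)[0]
    return GlobalRep(code, "bottleneck", {"code_dim": model.code_dim})


def bottleneck_accuracy(model: BottleneckModel, corpus) -> float:
    """Mean per-position reconstruction accuracy over a corpus."""
    codes = _pad_corpus(corpus, model.max_len, model.n_classes, model.n_classes - 1)
    x = np.eye(model.n_classes)[codes].reshape(len(corpus), -1)
    code, _ = model.encoder.forward(x)
    logits, _ = model.decoder.forward(code)
    pred = logits.reshape(len(corpus), model.max_len, model.n_classes).argmax(axis=2)
    return float((pred == codes).mean())
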