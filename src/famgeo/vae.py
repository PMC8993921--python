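"""Categorical VAE over aligned families with an entropy-calibrated decoder.

The model is a standard VAE with a Gaussian posterior over a low-dimensional
latent z (default d = 2) and a per-position categorical likelihood over the
C = 21 residue classes.  On top of the raw decoder sits an *entropy network*:
a proximity function

    alpha(z) = sigmoid(6.9077 * (beta - V(z)) / beta),
    V(z)     = min_j ||z - kappa_j||^2,

with trainable positive scale beta and cluster centers kappa_j initialized by
k-means on the training embeddings.  The decoded distribution is the convex
blend

    p(x|z) = alpha(z) * softmax(decoder(z)) + (1 - alpha(z)) / C,

so the output is exactly uniform (maximum entropy, L*ln C) far from the data
support and follows the trained decoder close to it.  Since
6.9077 ~ ln(999), alpha saturates at ~0.999 on the centers and ~0.001 at
V = 2*beta.  This calibration is what makes the induced Riemannian metric
(see :mod:`famgeo.geometry`) well behaved: curves are penalized for crossing
regions where the model has never seen data.

Training runs in two phases: (1) encoder + raw decoder by the reweighted
ELBO; (2) encoder frozen, centers set by k-means, beta (softplus
parametrized) and the raw decoder trained jointly on the blended likelihood.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.cluster import KMeans

from famgeo._nn import MLP, Adam, softmax, log_softmax, softplus, sigmoid
from famgeo.alphabet import Alphabet, PROTEIN
from famgeo.families import AlignedFamily, SequenceWeights

#: logit scale of the proximity sigmoid; ln(999), so alpha(V=0) ~ 0.999
ALPHA_SCALE = 6.9077


@dataclass
class TrainingConfig:
    d: int = 2
    hidden: int = 64
    n_hidden: int = 2
    K: int | None = None          # cluster centers; default min(50, N)
    phase1_epochs: int = 300
    phase2_epochs: int = 150
    lr: float = 2e-3
    kl_weight: float = 1.0

    def resolve_K(self, N: int) -> int:
        return self.K if self.K is not None else min(50, N)


@dataclass
class EntropyNetParams:
    """Proximity parameters: centers kappa (K, d) and softplus-raw beta."""

    centers: np.ndarray
    rho: float  # beta = softplus(rho) > 0

    @property
    def beta(self) -> float:
        return float(softplus(np.asarray(self.rho)))

    @property
    def K(self) -> int:
        return self.centers.shape[0]


class VaeModel:
    """Trained family VAE: encoder, raw decoder, entropy network."""

    def __init__(
        self,
        encoder: MLP,
        decoder: MLP,
        alphabet: Alphabet,
        L: int,
        d: int,
        entropy: EntropyNetParams | None = None,
        seed: int | None = None,
        config: TrainingConfig | None = None,
    ):
        self.encoder = encoder
        self.decoder = decoder
        self.alphabet = alphabet
        self.L = L
        self.C = alphabet.C
        self.d = d
        self.entropy = entropy
        self.seed = seed
        self.config = config
        self.train_ids: list = []
        self.train_embeddings: np.ndarray | None = None
        self.loss_history: dict = {"phase1": [], "phase2": []}

    # ---------------- encoding ----------------

    def _flat_onehot(self, rows: np.ndarray) -> np.ndarray:
        rows = np.asarray(rows)
        if rows.ndim == 1:
            rows = rows[None, :]
        if rows.shape[-1] == self.C and rows.ndim == 3:
            x = rows.reshape(rows.shape[0], -1).astype(np.float64)
        else:
            if rows.shape[1] != self.L:
                raise ValueError(f"sequence length {rows.shape[1]} != model L={self.L}")
            x = np.eye(self.C)[rows.astype(np.int64)].reshape(rows.shape[0], -1)
        return x

    def encode_batch(self, rows: np.ndarray):
        """Posterior means and variances for a batch of sequences."""
        x = self._flat_onehot(rows)
        out, _ = self.encoder.forward(x)
        mu, logvar = out[:, : self.d], np.clip(out[:, self.d :], -8.0, 8.0)
        return mu, np.exp(logvar)

    def encode(self, row: np.ndarray):
        """Posterior mean (the canonical embedding) and variance of one sequence."""
        mu, var = self.encode_batch(np.asarray(row)[None, ...])
        return mu[0], var[0]

    # ---------------- decoding ----------------

    def decode_raw_batch(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        logits, _ = self.decoder.forward(Z)
        return softmax(logits.reshape(Z.shape[0], self.L, self.C))

    def proximity_batch(self, Z: np.ndarray):
        """alpha(z) in [0, 1] and V(z) = min squared distance to the centers."""
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        if self.entropy is None:
            return np.ones(Z.shape[0]), np.zeros(Z.shape[0])
        diff = Z[:, None, :] - self.entropy.centers[None, :, :]
        V = np.min(np.sum(diff * diff, axis=2), axis=1)
        beta = self.entropy.beta
        alpha = sigmoid(ALPHA_SCALE * (beta - V) / beta)
        return alpha, V

    def proximity(self, z: np.ndarray):
        a, V = self.proximity_batch(np.asarray(z)[None, :])
        return float(a[0]), float(V[0])

    def decode_batch(self, Z: np.ndarray) -> np.ndarray:
        """Entropy-calibrated categorical outputs, shape (M, L, C)."""
        s = self.decode_raw_batch(Z)
        alpha, _ = self.proximity_batch(Z)
        return alpha[:, None, None] * s + (1.0 - alpha)[:, None, None] / self.C

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Position-categorical distribution (L, C) at a single latent point."""
        return self.decode_batch(np.asarray(z)[None, :])[0]

    def sequence_entropy_batch(self, Z: np.ndarray) -> np.ndarray:
        """Summed Shannon entropy (nats) of the decoded distribution."""
        p = self.decode_batch(Z)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        return -plogp.sum(axis=(1, 2))

    def sequence_entropy(self, z: np.ndarray) -> float:
        return float(self.sequence_entropy_batch(np.asarray(z)[None, :])[0])

    @property
    def max_entropy(self) -> float:
        return self.L * np.log(self.C)

    # ---------------- gradients through decode ----------------

    def decode_vjp(self, Z: np.ndarray, gprobs: np.ndarray) -> np.ndarray:
        """Vector-Jacobian product of decode_batch with respect to Z.

        Given upstream gradients on the blended probabilities (M, L, C),
        returns gradients on the latent points (M, d).  Used by the geodesic
        refinement; verified against finite differences in the test suite.
        """
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        M = Z.shape[0]
        logits, acts = self.decoder.forward(Z)
        s = softmax(logits.reshape(M, self.L, self.C))
        if self.entropy is not None:
            diff = Z[:, None, :] - self.entropy.centers[None, :, :]
            sq = np.sum(diff * diff, axis=2)
            jstar = np.argmin(sq, axis=1)
            V = sq[np.arange(M), jstar]
            beta = self.entropy.beta
            alpha = sigmoid(ALPHA_SCALE * (beta - V) / beta)
        else:
            alpha = np.ones(M)
        # blend: p = alpha*s + (1-alpha)/C
        g_s = alpha[:, None, None] * gprobs
        # softmax backward per position
        g_logits = s * (g_s - np.sum(g_s * s, axis=2, keepdims=True))
        _, gZ = self.decoder.backward(acts, g_logits.reshape(M, -1))
        if self.entropy is not None:
            g_alpha = np.sum(gprobs * (s - 1.0 / self.C), axis=(1, 2))
            dalpha_dV = alpha * (1.0 - alpha) * (-ALPHA_SCALE / beta)
            dV_dZ = 2.0 * (Z - self.entropy.centers[jstar])
            gZ = gZ + (g_alpha * dalpha_dV)[:, None] * dV_dZ
        return gZ

    # ---------------- persistence ----------------

    def save(self, path) -> None:
        arrays = {}
        for i, p in enumerate(self.encoder.params):
            arrays[f"enc_{i}"] = p
        for i, p in enumerate(self.decoder.params):
            arrays[f"dec_{i}"] = p
        if self.entropy is not None:
            arrays["centers"] = self.entropy.centers
            arrays["rho"] = np.asarray(self.entropy.rho)
        if self.train_embeddings is not None:
            arrays["train_embeddings"] = self.train_embeddings
        meta = {
            "version": 1,
            "enc_sizes": self.encoder.sizes,
            "dec_sizes": self.decoder.sizes,
            "alphabet": {"symbols": self.alphabet.symbols, "gap": self.alphabet.gap},
            "L": self.L,
            "d": self.d,
            "seed": self.seed,
            "config": asdict(self.config) if self.config else None,
            "train_ids": list(self.train_ids),
            "has_entropy": self.entropy is not None,
        }
        np.savez(path, meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "VaeModel":
        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["meta"]))
        rng = np.random.default_rng(0)
        enc = MLP(meta["enc_sizes"], rng)
        dec = MLP(meta["dec_sizes"], rng)
        enc.params = [data[f"enc_{i}"] for i in range(len(enc.params))]
        dec.params = [data[f"dec_{i}"] for i in range(len(dec.params))]
        alphabet = Alphabet(symbols=meta["alphabet"]["symbols"], gap=meta["alphabet"]["gap"])
        entropy = None
        if meta["has_entropy"]:
            entropy = EntropyNetParams(data["centers"], float(data["rho"]))
        cfg = TrainingConfig(**meta["config"]) if meta["config"] else None
        model = cls(enc, dec, alphabet, meta["L"], meta["d"], entropy, meta["seed"], cfg)
        model.train_ids = meta["train_ids"]
        if "train_embeddings" in data:
            model.train_embeddings = data["train_embeddings"]
        return model


def _elbo_pass(model, x, codes, w, rng, kl_weight, train=True, optimizer=None):
    """One full-batch ELBO forward/backward pass (phase 1)."""
    N = x.shape[0]
    d = model.d
    out, enc_acts = model.encoder.forward(x)
    mu, logvar = out[:, :d], np.clip(out[:, d:], -8.0, 8.0)
    eps = rng.standard_normal(mu.shape)
    z = mu + eps * np.exp(0.5 * logvar)
    logits, dec_acts = model.decoder.forward(z)
    logp = log_softmax(logits.reshape(N, model.L, model.C))
    idx_n = np.arange(N)[:, None]
    idx_l = np.arange(model.L)[None, :]
    rec = -logp[idx_n, idx_l, codes].sum(axis=1)
    kl = 0.5 * np.sum(mu**2 + np.exp(logvar) - 1.0 - logvar, axis=1)
    loss = float(np.sum(w * (rec + kl_weight * kl)))
    if not train:
        return loss
    # backward
    p = np.exp(logp)
    g_logits = p.copy()
    g_logits[idx_n, idx_l, codes] -= 1.0
    g_logits *= w[:, None, None]
    dec_grads, g_z = model.decoder.backward(dec_acts, g_logits.reshape(N, -1))
    g_mu = g_z + kl_weight * w[:, None] * mu
    g_logvar = (
        g_z * eps * 0.5 * np.exp(0.5 * logvar)
        + kl_weight * 0.5 * w[:, None] * (np.exp(logvar) - 1.0)
    )
    clip_mask = (out[:, d:] > -8.0) & (out[:, d:] < 8.0)
    g_out = np.concatenate([g_mu, g_logvar * clip_mask], axis=1)
    enc_grads, _ = model.encoder.backward(enc_acts, g_out)
    optimizer.step(enc_grads + dec_grads)
    return loss


def fit_vae(
    family: AlignedFamily,
    weights: SequenceWeights | None = None,
    config: TrainingConfig | None = None,
    seed: int = 0,
) -> VaeModel:
    """Train the entropy-calibrated VAE on an aligned family.

    Phase 1 fits encoder and raw decoder by the (optionally reweighted)
    ELBO with full-batch Adam; phase 2 freezes the encoder, initializes the
    entropy-network centers by k-means on the training posterior means, and
    trains beta together with the raw decoder on the blended likelihood.
    Identical seed, config and data give bit-identical parameters.
    """
    if family.N < 2:
        raise ValueError("need at least 2 sequences to train")
    config = config or TrainingConfig()
    K = config.resolve_K(family.N)
    if K > family.N:
        raise ValueError(f"K={K} cluster centers exceed N={family.N} sequences")
    rng = np.random.default_rng(seed)

    L, C, d = family.L, family.alphabet.C, config.d
    hid = [config.hidden] * config.n_hidden
    encoder = MLP([L * C] + hid + [2 * d], rng)
    decoder = MLP([d] + hid + [L * C], rng)
    model = VaeModel(encoder, decoder, family.alphabet, L, d, None, seed, config)

    x = model._flat_onehot(family.rows)
    codes = family.rows
    if weights is None:
        w = np.full(family.N, 1.0 / family.N)
    else:
        w = np.asarray(weights.w, dtype=np.float64)
        w = w / w.sum()

    # ---- phase 1: ELBO ----
    opt = Adam(encoder.params + decoder.params, lr=config.lr)
    for epoch in range(config.phase1_epochs):
        loss = _elbo_pass(model, x, codes, w, rng, config.kl_weight, True, opt)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite ELBO at phase-1 epoch {epoch}")
        model.loss_history["phase1"].append(loss)

    mu, _ = model.encode_batch(family.rows)
    model.train_ids = list(family.ids)
    model.train_embeddings = mu

    # ---- phase 2: entropy network ----
    km = KMeans(n_clusters=K, n_init=10, random_state=int(seed) % (2**31)).fit(mu)
    rho0 = 1.0  # beta = softplus(1) ~ 1.31, order of the k-means cell size
    model.entropy = EntropyNetParams(km.cluster_centers_.astype(np.float64), rho0)

    N = family.N
    idx_n = np.arange(N)[:, None]
    idx_l = np.arange(L)[None, :]
    diff = mu[:, None, :] - model.entropy.centers[None, :, :]
    sq = np.sum(diff * diff, axis=2)
    jstar = np.argmin(sq, axis=1)
    V = sq[np.arange(N), jstar]  # fixed: encoder and centers frozen in phase 2

    rho = np.array(rho0, dtype=np.float64)
    opt2 = Adam(decoder.params + [rho], lr=config.lr)
    for epoch in range(config.phase2_epochs):
        z = mu  # posterior means; encoder frozen
        beta = float(softplus(rho))
        alpha = sigmoid(ALPHA_SCALE * (beta - V) / beta)
        logits, dec_acts = decoder.forward(z)
        s = softmax(logits.reshape(N, L, C))
        p = alpha[:, None, None] * s + (1.0 - alpha)[:, None, None] / C
        ll = np.log(np.maximum(p[idx_n, idx_l, codes], 1e-300))
        loss = float(-np.sum(w[:, None] * ll))
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at phase-2 epoch {epoch}")
        model.loss_history["phase2"].append(loss)
        # backward: dloss/dp only at the true classes
        gp = np.zeros_like(p)
        gp[idx_n, idx_l, codes] = -w[:, None] / np.maximum(p[idx_n, idx_l, codes], 1e-300)
        g_s = alpha[:, None, None] * gp
        g_logits = s * (g_s - np.sum(g_s * s, axis=2, keepdims=True))
        dec_grads, _ = decoder.backward(dec_acts, g_logits.reshape(N, -1))
        g_alpha = np.sum(gp * (s - 1.0 / C), axis=(1, 2))
        du_dbeta = ALPHA_SCALE * V / beta**2
        g_beta = np.sum(g_alpha * alpha * (1.0 - alpha) * du_dbeta)
        g_rho = np.array(g_beta * sigmoid(float(rho)))
        opt2.step(dec_grads + [g_rho])
        model.entropy = EntropyNetParams(model.entropy.centers, float(rho))

    return model


def reconstruction_accuracy(
    model: VaeModel,
    family: AlignedFamily,
    subset=None,
    include_gaps: bool = True,
) -> np.ndarray:
    """Per-sequence fraction of positions whose decoded argmax matches the
    true residue, for encode-then-decode round trips.

    Gap positions count as an ordinary class by default; with
    ``include_gaps=False`` columns where the true residue is a gap are
    excluded from the per-sequence denominator.
    """
    ids = list(family.ids) if subset is None else list(subset)
    idx = [family.index_of(i) for i in ids]
    rows = family.rows[idx]
    mu, _ = model.encode_batch(rows)
    pred = np.argmax(model.decode_batch(mu), axis=2)
    correct = pred == rows
    if include_gaps:
        return correct.mean(axis=1)
    nongap = rows != family.alphabet.gap_index
    denom = np.maximum(nongap.sum(axis=1), 1)
    return (correct & nongap).sum(axis=1) / denom
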