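"""Encoder-decoder transformer autoencoder over SMILES token sequences.

The encoder maps a token sequence to a single d-dimensional latent vector by
mean-pooling the final encoder states over non-PAD positions. The decoder
cross-attends to that single latent (a length-1 memory) and predicts the
right-shifted target autoregressively under a causal mask.

Built on :mod:`simscreen.autodiff`; all weights are plain NumPy arrays.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor, embedding, layer_norm
from .tokenizer import BOS_ID, EOS_ID, PAD_ID, TokenSequence, Vocabulary, decode

logger = logging.getLogger(__name__)

NEG_INF = -1e9
DTYPE = np.float32  # model compute dtype; losses stay in the caller's dtype


@dataclass
class ModelConfig:
    d: int = 256
    n_layers: int = 4
    n_heads: int = 4
    feedforward_dim: int = 1024
    vocab_size: int = 0
    max_len: int = 128
    dropout: float = 0.1

    def __post_init__(self):
        if self.d <= 0 or self.n_layers <= 0 or self.n_heads <= 0:
            raise ValueError("model dimensions must be positive")
        if self.d % self.n_heads != 0:
            raise ValueError(f"d={self.d} not divisible by n_heads={self.n_heads}")

    @property
    def d_k(self) -> int:
        return self.d // self.n_heads


PROFILES = {
    # desk-scale profile for CPU tests
    "toy": dict(d=64, n_layers=2, n_heads=2, feedforward_dim=128, dropout=0.0,
                max_len=96),
    # full-size profile used for real screening runs
    "full": dict(d=256, n_layers=4, n_heads=4, feedforward_dim=1024,
                 dropout=0.1, max_len=128),
}


def positional_encoding(pos: int, dim_index: int, d: int) -> float:
    """Sinusoid value at one (position, embedding-dimension) point.

    Even dims carry sin(pos / 10000^(2i/d)), odd dims the matching cosine.
    """
    if not 0 <= dim_index < d:
        raise ValueError(f"dim_index {dim_index} outside [0, {d})")
    i = dim_index // 2
    angle = pos / (10000.0 ** (2.0 * i / d))
    return math.sin(angle) if dim_index % 2 == 0 else math.cos(angle)


def positional_encoding_table(max_len: int, d: int) -> np.ndarray:
    """[max_len, d] table of the sinusoidal encoding."""
    pos = np.arange(max_len)[:, None].astype(np.float64)
    i = np.arange(d)[None, :] // 2
    angle = pos / np.power(10000.0, 2.0 * i / d)
    table = np.where(np.arange(d)[None, :] % 2 == 0, np.sin(angle), np.cos(angle))
    return table


def scaled_dot_product_attention(Q, K, V, mask=None):
    """softmax(QK^T / sqrt(d_k)) V with optional boolean mask.

    `mask` is True where attention is *allowed*; masked positions get zero
    weight. Accepts Tensors or ndarrays (wrapped as constants); leading batch
    dimensions broadcast.
    """
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    d_k = Q.shape[-1]
    scores = (Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)) \
        * (1.0 / math.sqrt(d_k))
    if mask is not None:
        bias = np.where(np.asarray(mask, dtype=bool), 0.0, NEG_INF).astype(Q.data.dtype)
        scores = scores + bias
    attn = scores.softmax(axis=-1)
    return attn @ V


_CAUSAL_CACHE: dict = {}


def _causal_mask(T: int) -> "np.ndarray":
    if T not in _CAUSAL_CACHE:
        _CAUSAL_CACHE[T] = np.tril(np.ones((T, T), dtype=bool))[None, None]
    return _CAUSAL_CACHE[T]


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class _Params(dict):
    """Named parameter store: name -> Tensor(requires_grad=True)."""

    def add(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(array, dtype=DTYPE), requires_grad=True)
        self[name] = t
        return t


class TransformerAutoencoder:
    """Sequence autoencoder with a single-vector latent bottleneck."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 latent_scale_init: float = 1.0):
        if config.vocab_size < 5:
            raise ValueError("vocab_size must cover the special tokens")
        self.config = config
        self.seed = seed
        self.latent_scale_init = float(latent_scale_init)
        self.training = False
        self._dropout_rng = np.random.default_rng(seed + 101)
        self.params = _Params()
        self._init_weights(np.random.default_rng(seed))
        self.pe = positional_encoding_table(config.max_len, config.d).astype(DTYPE)

    # ------------------------------------------------------------------
    def _init_weights(self, rng: np.random.Generator) -> None:
        c = self.config
        p = self.params
        p.add("embed", rng.normal(0.0, 1.0 / math.sqrt(c.d), (c.vocab_size, c.d)))
        for side in ("enc", "dec"):
            for layer in range(c.n_layers):
                pre = f"{side}{layer}"
                blocks = ["self"] if side == "enc" else ["self", "cross"]
                for blk in blocks:
                    # q/k/v projections fused column-wise into one matmul;
                    # blocks drawn independently to match per-matrix Xavier
                    qkv = np.concatenate(
                        [_xavier(rng, c.d, c.d) for _ in range(3)], axis=1)
                    p.add(f"{pre}.{blk}.qkv", qkv)
                    p.add(f"{pre}.{blk}.qkvb", np.zeros(3 * c.d))
                    p.add(f"{pre}.{blk}.o", _xavier(rng, c.d, c.d))
                    p.add(f"{pre}.{blk}.ob", np.zeros(c.d))
                p.add(f"{pre}.ff.w1", _xavier(rng, c.d, c.feedforward_dim))
                p.add(f"{pre}.ff.b1", np.zeros(c.feedforward_dim))
                p.add(f"{pre}.ff.w2", _xavier(rng, c.feedforward_dim, c.d))
                p.add(f"{pre}.ff.b2", np.zeros(c.d))
                n_norms = 2 if side == "enc" else 3
                for k in range(n_norms):
                    p.add(f"{pre}.ln{k}.g", np.ones(c.d))
                    p.add(f"{pre}.ln{k}.b", np.zeros(c.d))
        p.add("out.w", _xavier(rng, c.d, c.vocab_size))
        p.add("out.b", np.zeros(c.vocab_size))
        # the pooled latent inherits the scale of the last encoder norm;
        # seeding its gain near the shape-loss target scale lets training
        # fit structure instead of spending epochs growing norms
        last = f"enc{c.n_layers - 1}.ln1.g"
        self.params[last].data = (self.params[last].data
                                  * np.asarray(self.latent_scale_init,
                                               dtype=DTYPE))

    # ------------------------------------------------------------------
    def train_mode(self, on: bool = True) -> None:
        self.training = on

    def parameters(self):
        return list(self.params.values())

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    # ------------------------------------------------------------------
    def _dropout(self, x: Tensor) -> Tensor:
        rate = self.config.dropout
        if not self.training or rate <= 0.0:
            return x
        keep = ((self._dropout_rng.random(x.shape) >= rate) / (1.0 - rate)).astype(x.data.dtype)
        return x * keep

    def _layer_norm(self, x: Tensor, prefix: str) -> Tensor:
        return layer_norm(x, self.params[f"{prefix}.g"],
                          self.params[f"{prefix}.b"])

    def _mha(self, prefix: str, x_q: Tensor, x_kv: Tensor, bias) -> Tensor:
        """Multi-head attention block (shared by self- and cross-attention).

        `bias` is an additive attention-logit array (0 where allowed,
        NEG_INF where masked) or None; computed once per forward pass.
        """
        c = self.config
        p = self.params
        B, Tq = x_q.shape[0], x_q.shape[1]
        same = x_q is x_kv

        def split_heads(t, T):
            return t.reshape(B, T, c.n_heads, c.d_k).transpose(0, 2, 1, 3)

        W, b = p[f"{prefix}.qkv"], p[f"{prefix}.qkvb"]
        if same:
            qkv = x_q @ W + b
            q = split_heads(qkv[:, :, : c.d], Tq)
            k = split_heads(qkv[:, :, c.d:2 * c.d], Tq)
            v = split_heads(qkv[:, :, 2 * c.d:], Tq)
        else:
            Tk = x_kv.shape[1]
            q = split_heads(x_q @ W[:, : c.d] + b[: c.d], Tq)
            kv = x_kv @ W[:, c.d:] + b[c.d:]
            k = split_heads(kv[:, :, : c.d], Tk)
            v = split_heads(kv[:, :, c.d:], Tk)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(c.d_k))
        if bias is not None:
            scores = scores + bias
        ctx = scores.softmax(axis=-1) @ v
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, Tq, c.d)
        return ctx @ p[f"{prefix}.o"] + p[f"{prefix}.ob"]

    def _ffn(self, prefix: str, x: Tensor) -> Tensor:
        p = self.params
        h = (x @ p[f"{prefix}.w1"] + p[f"{prefix}.b1"]).relu()
        return h @ p[f"{prefix}.w2"] + p[f"{prefix}.b2"]

    def _embed(self, ids: np.ndarray) -> Tensor:
        c = self.config
        emb = embedding(self.params["embed"], ids) * math.sqrt(c.d)
        emb = emb + self.pe[: ids.shape[1]][None, :, :]
        return self._dropout(emb)

    # ------------------------------------------------------------------
    def encode(self, ids: np.ndarray) -> Tensor:
        """Token id batch [B, T] -> latent batch [B, d] (masked mean pool)."""
        ids = np.atleast_2d(np.asarray(ids))
        if ids.shape[1] > self.config.max_len:
            raise ValueError(
                f"sequence length {ids.shape[1]} exceeds max_len {self.config.max_len}")
        pad_mask = (ids != PAD_ID)  # [B, T]
        bias = np.where(pad_mask[:, None, None, :], 0.0,
                        NEG_INF).astype(DTYPE)
        x = self._embed(ids)
        for layer in range(self.config.n_layers):
            pre = f"enc{layer}"
            x = self._layer_norm(
                x + self._dropout(self._mha(f"{pre}.self", x, x, bias)),
                f"{pre}.ln0")
            x = self._layer_norm(x + self._dropout(self._ffn(f"{pre}.ff", x)),
                                 f"{pre}.ln1")
        keep = pad_mask[:, :, None].astype(x.data.dtype)
        counts = keep.sum(axis=1)  # [B, 1]
        return (x * keep).sum(axis=1) / counts

    def decode(self, latent: Tensor, dec_in: np.ndarray) -> Tensor:
        """Latent [B, d] + shifted target ids [B, T] -> logits [B, T, V]."""
        dec_in = np.atleast_2d(np.asarray(dec_in))
        B, T = dec_in.shape
        latent = latent if isinstance(latent, Tensor) else Tensor(latent)
        if latent.ndim == 1:
            latent = latent.reshape(1, latent.shape[0])
        memory = latent.reshape(B, 1, self.config.d)
        causal = _causal_mask(T)
        pad_ok = (dec_in != PAD_ID)[:, None, None, :]
        self_mask = causal & pad_ok
        # guarantee >= 1 unmasked key per query (the diagonal)
        self_mask = self_mask | np.eye(T, dtype=bool)[None, None, :, :]
        self_bias = np.where(self_mask, 0.0, NEG_INF).astype(DTYPE)
        x = self._embed(dec_in)
        for layer in range(self.config.n_layers):
            pre = f"dec{layer}"
            x = self._layer_norm(
                x + self._dropout(self._mha(f"{pre}.self", x, x, self_bias)),
                f"{pre}.ln0")
            x = self._layer_norm(
                x + self._dropout(self._mha(f"{pre}.cross", x, memory, None)),
                f"{pre}.ln1")
            x = self._layer_norm(x + self._dropout(self._ffn(f"{pre}.ff", x)),
                                 f"{pre}.ln2")
        return x @ self.params["out.w"] + self.params["out.b"]

    # ------------------------------------------------------------------
    def encode_to_latent(self, seq: TokenSequence | np.ndarray) -> np.ndarray:
        """Single-sequence latent vector (evaluation mode, detached)."""
        ids = np.asarray(seq.ids if isinstance(seq, TokenSequence) else seq)
        was_training = self.training
        self.training = False
        try:
            latent = self.encode(ids[None, :] if ids.ndim == 1 else ids)
        finally:
            self.training = was_training
        out = latent.data
        return out[0] if ids.ndim == 1 else out

    def decode_logits(self, latent, shifted_target) -> np.ndarray:
        """Per-position vocabulary probabilities for a shifted target."""
        ids = np.asarray(
            shifted_target.ids if isinstance(shifted_target, TokenSequence)
            else shifted_target)
        single = ids.ndim == 1
        was_training = self.training
        self.training = False
        try:
            logits = self.decode(Tensor(np.atleast_2d(latent)),
                                 ids[None, :] if single else ids)
        finally:
            self.training = was_training
        probs = logits.softmax(axis=-1).data
        return probs[0] if single else probs

    def greedy_reconstruct(self, latent: np.ndarray, vocab: Vocabulary,
                           max_len: int | None = None) -> str:
        """Autoregressive argmax decoding from a latent vector."""
        max_len = max_len or self.config.max_len
        was_training = self.training
        self.training = False
        try:
            seq = [BOS_ID]
            for _ in range(max_len - 1):
                logits = self.decode(Tensor(np.atleast_2d(latent)),
                                     np.array([seq]))
                nxt = int(np.argmax(logits.data[0, -1]))
                if nxt == EOS_ID:
                    break
                seq.append(nxt)
            else:
                logger.info("greedy decode truncated at max_len=%d", max_len)
        finally:
            self.training = was_training
        return decode(seq + [EOS_ID], vocab)

    def greedy_reconstruct_batch(self, latents: np.ndarray,
                                 vocab: Vocabulary,
                                 max_len: int | None = None) -> list:
        """Greedy decoding for a whole latent batch at once."""
        max_len = max_len or self.config.max_len
        latents = np.atleast_2d(latents)
        B = latents.shape[0]
        was_training = self.training
        self.training = False
        try:
            seqs = np.full((B, 1), BOS_ID, dtype=np.int64)
            done = np.zeros(B, dtype=bool)
            for _ in range(max_len - 1):
                logits = self.decode(Tensor(latents), seqs)
                nxt = logits.data[:, -1, :].argmax(axis=1)
                nxt[done] = PAD_ID
                done |= nxt == EOS_ID
                seqs = np.concatenate([seqs, nxt[:, None]], axis=1)
                if done.all():
                    break
        finally:
            self.training = was_training
        out = []
        for row in seqs:
            ids = [int(t) for t in row if t != PAD_ID]
            out.append(decode(ids + [EOS_ID], vocab))
        return out

    # ------------------------------------------------------------------
    def save(self, path, vocab: Vocabulary, extra: dict | None = None) -> None:
        """Checkpoint = .npz weights + .json sidecar (config, vocab, seed)."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path.with_suffix(".npz"),
                            **{k: t.data for k, t in self.params.items()})
        meta = {
            "config": asdict(self.config),
            "seed": self.seed,
            "latent_scale_init": self.latent_scale_init,
            "vocab_hash": vocab.content_hash(),
            "vocab": vocab.token_to_id,
        }
        if extra:
            meta["extra"] = extra
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path, vocab: Vocabulary | None = None):
        """Load checkpoint; refuses on vocabulary mismatch.

        Returns (model, vocab). If `vocab` is given it must hash-match the
        checkpoint's; otherwise the stored vocabulary is reconstructed.
        """
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        stored_vocab = Vocabulary(token_to_id=meta["vocab"])
        if vocab is not None and vocab.content_hash() != meta["vocab_hash"]:
            raise ValueError("vocabulary hash mismatch with checkpoint")
        vocab = vocab or stored_vocab
        model = cls(ModelConfig(**meta["config"]), seed=meta["seed"],
                    latent_scale_init=meta.get("latent_scale_init", 1.0))
        weights = np.load(path.with_suffix(".npz"))
        for k, t in model.params.items():
            t.data = np.array(weights[k], dtype=DTYPE)
        model.pe = positional_encoding_table(model.config.max_len, model.config.d).astype(DTYPE)
        return model, vocab


def checkpoint_hash(path) -> str:
    data = Path(path).with_suffix(".npz").read_bytes()
    return hashlib.sha256(data).hexdigest()[:16]
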