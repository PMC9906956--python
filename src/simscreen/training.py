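"""Anchor-aware batching and the training loop for the three model variants
(`vanilla`, `triplet`, `similarity`).

Each batch pairs a token matrix with the anchor indices drawn for it and the
matching slice of the precomputed ground-truth similarity matrix; the shape
term (triplet or similarity loss) is computed on the batch latents and added
to the reconstruction cross entropy.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import losses as L
from .chem import SimilarityMatrix, cached_similarity_matrix, tanimoto_metric
from .model import PROFILES, ModelConfig, TransformerAutoencoder
from .tokenizer import PAD_ID, Vocabulary, build_vocabulary, encode_batch

logger = logging.getLogger(__name__)

LOSS_NAMES = ("vanilla", "triplet", "similarity")


@dataclass
class TrainConfig:
    loss_name: str = "similarity"
    epochs: int = 60
    batch_size: int = 32
    anchors_per_batch: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    profile: str = "toy"
    scaling_factor: float = 20.0
    margin: float = 1.0
    pos_threshold: float = 0.5
    shape_weight: float = 1.0
    validation_fraction: float = 0.1
    validation_stride: int = 1   # compute val loss every k-th epoch
    grad_clip: float = 1.0
    fp_radius: int = 2
    fp_bits: int = 2048
    max_len: int | None = None

    def __post_init__(self):
        if self.loss_name not in LOSS_NAMES:
            raise ValueError(f"loss_name must be one of {LOSS_NAMES}")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if not 0 < self.anchors_per_batch < self.batch_size:
            raise ValueError("need 0 < anchors_per_batch < batch_size")
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")


@dataclass
class TrainedModel:
    model: TransformerAutoencoder
    vocab: Vocabulary
    config: TrainConfig
    checkpoint: Path | None = None
    history: list = field(default_factory=list)

    @property
    def final_losses(self) -> dict:
        return self.history[-1] if self.history else {}


class Adam:
    """Adam with global gradient-norm clipping."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8,
                 clip: float = 1.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.clip = lr, betas, eps, clip
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if self.clip and self.clip > 0:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip:
                scale = self.clip / (total + 1e-12)
                grads = [g * scale for g in grads]
        self.t += 1
        b1, b2 = self.betas
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_validation_split(n: int, validation_fraction: float,
                           seed: int) -> tuple:
    """Seeded split by molecule index; returns (train_idx, val_idx)."""
    rng = np.random.default_rng(seed + 7919)
    perm = rng.permutation(n)
    n_val = max(1, int(round(n * validation_fraction)))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def make_batches(n: int, batch_size: int, anchors_per_batch: int,
                 rng: np.random.Generator, sims: np.ndarray | None = None,
                 group_size: int = 8):
    """One epoch of (batch indices, anchor positions) pairs.

    Every molecule appears once per epoch (last partial batch dropped);
    anchors are sampled uniformly without replacement within each batch.

    When `sims` is given, batches are assembled from similarity groups: a
    random unassigned seed plus its most similar unassigned neighbours.
    Random batches of a few hundred diverse molecules contain almost no
    high-similarity pairs, so the shape losses would never see the
    fine-grained neighbourhoods they are supposed to embed; grouping is the
    batch-construction counterpart of anchor selection.
    """
    if n < batch_size:
        raise ValueError(f"dataset size {n} < batch_size {batch_size}")
    if sims is None:
        perm = rng.permutation(n)
        for start in range(0, n - batch_size + 1, batch_size):
            batch = perm[start:start + batch_size]
            anchors = rng.choice(batch_size, size=anchors_per_batch,
                                 replace=False)
            yield batch, anchors
        return

    order = list(rng.permutation(n))
    unassigned = set(order)
    batches = []
    current: list[int] = []
    for seed in order:
        if seed not in unassigned:
            continue
        group = [seed]
        unassigned.discard(seed)
        take = min(group_size - 1, batch_size - len(current) - 1)
        if take > 0 and unassigned:
            pool = np.fromiter(unassigned, dtype=np.int64)
            nearest = pool[np.argsort(-sims[seed, pool], kind="stable")[:take]]
            for j in nearest:
                group.append(int(j))
                unassigned.discard(int(j))
        current.extend(group)
        if len(current) >= batch_size:
            batches.append(np.array(current[:batch_size]))
            current = current[batch_size:]
    for batch in batches:
        anchors = rng.choice(batch_size, size=anchors_per_batch, replace=False)
        yield batch, anchors


def _trim(tokens: np.ndarray) -> np.ndarray:
    """Drop all-PAD tail columns (latents are padding-invariant)."""
    keep = np.where((tokens != PAD_ID).any(axis=0))[0]
    return tokens[:, : keep[-1] + 1]


def fit(dataset: list, config: TrainConfig,
        sims: SimilarityMatrix | None = None,
        out_dir=None, metric=None) -> TrainedModel:
    """Train one model variant; deterministic for a fixed seed on one device.

    `sims` may be a precomputed similarity matrix aligned with `dataset`
    order; it is computed (and cached under `out_dir`) when absent and a
    shape loss requires it.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "train_config.json").write_text(
            json.dumps(asdict(config), indent=1))

    vocab = build_vocabulary(dataset)
    profile = dict(PROFILES[config.profile])
    if config.max_len:
        profile["max_len"] = config.max_len
    model_cfg = ModelConfig(vocab_size=len(vocab), **profile)
    scale_init = 1.0
    if config.loss_name == "similarity":
        # match the latent's initial scale to the shape-loss target scale
        scale_init = max(1.0, config.scaling_factor / np.sqrt(model_cfg.d))
    model = TransformerAutoencoder(model_cfg, seed=config.seed,
                                   latent_scale_init=scale_init)

    needs_sims = config.loss_name in ("triplet", "similarity")
    if needs_sims and sims is None:
        metric = metric or tanimoto_metric(config.fp_radius, config.fp_bits)
        sims = cached_similarity_matrix(dataset, metric, cache_dir=out_dir)
    if sims is not None and list(sims.ids) != [r.mol_id for r in dataset]:
        raise ValueError("similarity matrix ids do not match dataset order")

    tokens = encode_batch([r.smiles for r in dataset], vocab, model_cfg.max_len)
    train_idx, val_idx = train_validation_split(
        len(dataset), config.validation_fraction, config.seed)
    if len(train_idx) < config.batch_size:
        raise ValueError("training split smaller than batch_size")

    opt = Adam(model.parameters(), lr=config.learning_rate,
               clip=config.grad_clip)
    sim_params = L.SimilarityLossParams(a=config.scaling_factor)
    tri_params = L.TripletParams(m=config.margin)

    sims_train = (sims.values[np.ix_(train_idx, train_idx)]
                  if needs_sims else None)
    history: list[dict] = []
    best_val = np.inf
    ckpt = out_dir / "checkpoint" if out_dir else None
    metrics_path = out_dir / "metrics.csv" if out_dir else None
    if metrics_path:
        metrics_path.write_text(
            "epoch,train_loss,train_recon,train_shape,val_loss\n")

    for epoch in range(1, config.epochs + 1):
        model.train_mode(True)
        ep_loss = ep_recon = ep_shape = 0.0
        n_batches = 0
        for batch, anchors in make_batches(
                len(train_idx), config.batch_size,
                config.anchors_per_batch, rng, sims=sims_train):
            idx = train_idx[batch]
            tok = _trim(tokens[idx])
            latents = model.encode(tok)
            logits = model.decode(latents, tok[:, :-1])
            recon = L.logits_reconstruction_loss(logits, tok[:, 1:],
                                                 reduction="mean")
            if config.loss_name == "similarity":
                shape = L.batch_similarity_loss(
                    latents, anchors, sims.values[np.ix_(idx, idx)],
                    params=sim_params)
            elif config.loss_name == "triplet":
                shape = L.batch_triplet_loss(
                    latents, anchors, sims.values[np.ix_(idx, idx)],
                    params=tri_params, pos_threshold=config.pos_threshold)
            else:
                shape = L.Tensor(0.0)
            loss = L.combined_loss(recon, shape, weight=config.shape_weight)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"divergence at epoch {epoch}: loss={loss.item()} "
                    f"(recon={recon.item()}, shape={shape.item()})")
            model.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            ep_recon += recon.item()
            ep_shape += shape.item()
            n_batches += 1

        evaluated = (epoch % config.validation_stride == 0
                     or epoch == config.epochs)
        if evaluated:
            val_loss = _validation_loss(model, tokens[val_idx])
        else:
            val_loss = history[-1]["val_loss"] if history else np.inf
        row = {
            "epoch": epoch,
            "train_loss": ep_loss / n_batches,
            "train_recon": ep_recon / n_batches,
            "train_shape": ep_shape / n_batches,
            "val_loss": val_loss,
        }
        history.append(row)
        if metrics_path:
            with metrics_path.open("a") as fh:
                csv.writer(fh).writerow(
                    [row[k] for k in ("epoch", "train_loss", "train_recon",
                                      "train_shape", "val_loss")])
        logger.info("epoch %d: train %.4f (recon %.4f shape %.4f) val %.4f",
                    epoch, row["train_loss"], row["train_recon"],
                    row["train_shape"], val_loss)
        if ckpt is not None and evaluated and val_loss < best_val:
            best_val = val_loss
            model.save(ckpt, vocab, extra={"epoch": epoch,
                                           "val_loss": val_loss,
                                           "train_config": asdict(config)})

    model.train_mode(False)
    if ckpt is not None:
        model, vocab = TransformerAutoencoder.load(ckpt, vocab)
        vocab.save(ckpt.with_suffix(".vocab.json"))
    return TrainedModel(model=model, vocab=vocab, config=config,
                        checkpoint=ckpt, history=history)


def _validation_loss(model: TransformerAutoencoder,
                     tokens: np.ndarray) -> float:
    """Mean per-token reconstruction cross entropy on held-out molecules."""
    model.train_mode(False)
    tok = _trim(tokens)
    total, count = 0.0, 0
    for start in range(0, len(tok), 32):
        chunk = tok[start:start + 32]
        latents = model.encode(chunk)
        logits = model.decode(latents, chunk[:, :-1])
        keep = int((chunk[:, 1:] != PAD_ID).sum())
        nll = L.logits_reconstruction_loss(logits, chunk[:, 1:],
                                           reduction="sum")
        total += nll.item()
        count += keep
    return total / max(count, 1)
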