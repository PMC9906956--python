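"""Latent-space similarity search: embed a library, rank by exact L2
distance to a query latent, and rescale distances to approximate similarities
(s ~= 1 - d/d_max).

Ranking is exact (full distance computation + partial selection), never an
approximate nearest-neighbour index: the method reduces the *search space*,
it must not itself approximate ranks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import MoleculeRecord
from .model import TransformerAutoencoder, checkpoint_hash
from .tokenizer import Vocabulary, encode_batch

logger = logging.getLogger(__name__)


@dataclass
class EmbeddedLibrary:
    latents: np.ndarray          # [n, d]
    mol_ids: list
    smiles: list
    model_hash: str = ""

    def __post_init__(self):
        self.latents = np.asarray(self.latents, dtype=np.float64)
        if self.latents.shape[0] != len(self.mol_ids):
            raise ValueError("latent row count != molecule count")

    def __len__(self):
        return self.latents.shape[0]

    def index_of(self, mol_id: str) -> int:
        return self.mol_ids.index(mol_id)

    def save(self, path) -> None:
        """Binary array archive + JSON sidecar (id order, model hash)."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), latents=self.latents)
        path.with_suffix(".json").write_text(json.dumps({
            "mol_ids": self.mol_ids,
            "smiles": self.smiles,
            "model_hash": self.model_hash,
        }))

    @classmethod
    def load(cls, path) -> "EmbeddedLibrary":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        latents = np.load(path.with_suffix(".npz"))["latents"]
        return cls(latents=latents, mol_ids=meta["mol_ids"],
                   smiles=meta["smiles"], model_hash=meta["model_hash"])


@dataclass
class SearchResult:
    mol_ids: list
    distances: np.ndarray         # ascending
    approx_similarities: np.ndarray | None = None

    def to_frame(self, library: EmbeddedLibrary | None = None) -> pd.DataFrame:
        rows = {
            "rank": np.arange(1, len(self.mol_ids) + 1),
            "mol_id": self.mol_ids,
            "distance": self.distances,
        }
        if library is not None:
            smap = dict(zip(library.mol_ids, library.smiles))
            rows["smiles"] = [smap[m] for m in self.mol_ids]
        if self.approx_similarities is not None:
            rows["approx_similarity"] = self.approx_similarities
        return pd.DataFrame(rows)


def embed_records(records, model: TransformerAutoencoder, vocab: Vocabulary,
                  batch_size: int = 32) -> np.ndarray:
    """[n, d] latent matrix, batched; deterministic (eval mode)."""
    model.train_mode(False)
    out = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        tokens = encode_batch([r.smiles for r in chunk], vocab,
                              model.config.max_len)
        out.append(model.encode_to_latent(tokens))
    return np.vstack(out).astype(np.float64)


def embed_library(records, model: TransformerAutoencoder, vocab: Vocabulary,
                  batch_size: int = 32, model_hash: str = "") -> EmbeddedLibrary:
    latents = embed_records(records, model, vocab, batch_size=batch_size)
    return EmbeddedLibrary(latents=latents,
                           mol_ids=[r.mol_id for r in records],
                           smiles=[r.smiles for r in records],
                           model_hash=model_hash)


def embed_library_from_checkpoint(records, checkpoint_path,
                                  batch_size: int = 32) -> EmbeddedLibrary:
    model, vocab = TransformerAutoencoder.load(checkpoint_path)
    return embed_library(records, model, vocab, batch_size=batch_size,
                         model_hash=checkpoint_hash(checkpoint_path))


def _ranked(distances: np.ndarray, mol_ids: list, N: int) -> tuple:
    """Exact top-N by distance; ties broken by lexicographic mol_id."""
    order = sorted(range(len(mol_ids)), key=lambda i: (distances[i], mol_ids[i]))
    top = order[:N]
    return [mol_ids[i] for i in top], distances[top]


def query_latent(ref_latent: np.ndarray, library: EmbeddedLibrary,
                 N: int, d_max: float | None = None) -> SearchResult:
    """Rank library molecules by L2 distance to a reference latent."""
    if N < 1:
        raise ValueError("N must be >= 1")
    if N > len(library):
        logger.warning("N=%d exceeds library size %d; returning full ranking",
                       N, len(library))
        N = len(library)
    diffs = library.latents - np.asarray(ref_latent, dtype=np.float64)
    distances = np.sqrt((diffs * diffs).sum(axis=1))
    ids, dists = _ranked(distances, library.mol_ids, N)
    approx = None
    if d_max is not None:
        approx = np.array([approx_similarity(d, d_max) for d in dists])
    return SearchResult(mol_ids=ids, distances=dists,
                        approx_similarities=approx)


def query(ref: MoleculeRecord, library: EmbeddedLibrary,
          model: TransformerAutoencoder, vocab: Vocabulary, N: int,
          d_max: float | None = None) -> SearchResult:
    """Embed a reference molecule and rank the library against it."""
    ref_latent = embed_records([ref], model, vocab)[0]
    return query_latent(ref_latent, library, N, d_max=d_max)


def approx_similarity(d_ij: float, d_max: float) -> float:
    """Rescale a latent distance into [0, 1]: 1 - d_ij/d_max."""
    if d_max == 0:
        logger.warning("degenerate library: d_max == 0; similarity := 1.0")
        return 1.0
    if d_max < 0 or d_ij < 0 or d_ij > d_max:
        raise ValueError(f"require 0 <= d_ij <= d_max, got {d_ij}, {d_max}")
    return 1.0 - d_ij / d_max


def max_pairwise_distance(library: EmbeddedLibrary, exact_below: int = 2000,
                          n_sample_pairs: int = 10000,
                          seed: int = 0) -> float:
    """d_max for the rescaling: exact for small libraries, else the max over
    a seeded random sample of pairs."""
    X = library.latents
    n = len(library)
    if n < 2:
        return 0.0
    if n <= exact_below:
        sq = (X * X).sum(axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        return float(np.sqrt(max(d2.max(), 0.0)))
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=n_sample_pairs)
    j = rng.integers(0, n, size=n_sample_pairs)
    d = np.sqrt(((X[i] - X[j]) ** 2).sum(axis=1))
    return float(d.max())
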