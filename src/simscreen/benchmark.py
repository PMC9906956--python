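"""Desk-scale benchmark protocol shared by the acceptance tests and the
acceptance report script.

Trains the three model variants (plus the scaling-factor ablation) on the
default clustered fixture dataset over several seeds and evaluates the
threshold-AUROC protocol and top-k reproduction curves on validation
references. All parameters are fixed here so every consumer measures the
same quantities.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .chem import similarity_matrix, tanimoto_metric
from .evaluation import (choose_references, threshold_auroc_protocol,
                         topk_reproduction_curve)
from .fixtures import FixtureSpec, generate_dataset
from .search import embed_library
from .training import TrainConfig, fit, train_validation_split

logger = logging.getLogger(__name__)

THRESHOLDS = [0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95]
SEEDS = (1, 2, 3)
EPOCHS = 85
BATCH_SIZE = 32
ANCHORS = 16
N_REFERENCES = 30
MIN_SIM = 0.40
TOPK_GRID = [10, 25, 50, 100, 200]

VARIANTS = {
    "vanilla": dict(loss_name="vanilla"),
    "triplet": dict(loss_name="triplet"),
    "similarity": dict(loss_name="similarity", scaling_factor=20.0),
    "similarity_a1": dict(loss_name="similarity", scaling_factor=1.0),
}


@dataclass
class VariantResult:
    per_threshold: dict          # threshold -> 3-seed mean AUROC
    per_seed_mean: list          # mean AUROC per seed (over thresholds)
    topk_mean: np.ndarray        # seed-averaged reproduction curve

    @property
    def overall(self) -> float:
        return float(np.mean(list(self.per_threshold.values())))


@dataclass
class BenchmarkReport:
    variants: dict = field(default_factory=dict)   # name -> VariantResult
    thresholds: list = field(default_factory=lambda: list(THRESHOLDS))
    seeds: tuple = SEEDS


def benchmark_dataset():
    records, manifest = generate_dataset(FixtureSpec())
    sims = similarity_matrix(records, tanimoto_metric())
    return records, manifest, sims


def train_variant(records, sims, name: str, seed: int,
                  epochs: int = EPOCHS):
    params = VARIANTS[name]
    cfg = TrainConfig(batch_size=BATCH_SIZE, anchors_per_batch=ANCHORS,
                      epochs=epochs, seed=seed, validation_stride=5,
                      **params)
    return fit(records, cfg, sims=sims)


def evaluate_variant(records, sims, trained, seed: int):
    """(AurocReport, RetrievalCurve) for one trained model / seed."""
    library = embed_library(records, trained.model, trained.vocab)
    _, val_idx = train_validation_split(
        len(records), trained.config.validation_fraction, seed)
    refs = choose_references(np.random.default_rng(seed + 31), val_idx,
                             N_REFERENCES)
    report = threshold_auroc_protocol(library, sims.values, refs,
                                      THRESHOLDS, MIN_SIM)
    grid = [n for n in TOPK_GRID if n <= len(records) - 1]
    curve = topk_reproduction_curve(library, sims.values, refs, grid, k=10)
    return report, curve


def run_benchmark(variant_names=None, epochs: int = EPOCHS,
                  seeds=SEEDS) -> BenchmarkReport:
    """Train and evaluate the requested variants; the full protocol."""
    variant_names = variant_names or list(VARIANTS)
    records, _, sims = benchmark_dataset()
    out = BenchmarkReport()
    for name in variant_names:
        per_threshold_rows = []
        per_seed_mean = []
        curves = []
        for seed in seeds:
            t0 = time.time()
            trained = train_variant(records, sims, name, seed, epochs=epochs)
            report, curve = evaluate_variant(records, sims, trained, seed)
            row = [report.mean[t] for t in THRESHOLDS]
            if any(v is None for v in row):
                missing = [t for t, v in zip(THRESHOLDS, row) if v is None]
                raise RuntimeError(
                    f"{name} seed {seed}: no usable reference at {missing}")
            per_threshold_rows.append(row)
            per_seed_mean.append(float(np.mean(row)))
            curves.append(curve.mean)
            logger.info("%s seed %d: mean AUROC %.3f (%.0fs)",
                        name, seed, per_seed_mean[-1], time.time() - t0)
        mean_rows = np.mean(per_threshold_rows, axis=0)
        out.variants[name] = VariantResult(
            per_threshold={t: float(v)
                           for t, v in zip(THRESHOLDS, mean_rows)},
            per_seed_mean=per_seed_mean,
            topk_mean=np.mean(curves, axis=0))
    return out
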